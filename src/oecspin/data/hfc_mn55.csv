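model,A1_MHz,site1,A2_MHz,site2,A3_MHz,site3,A4_MHz,site4,ratio12,ratio23,ratio34
A4,448,4,216,3,189,2,188,1,2.07,1.14,1.01
A5,416,1,235,4,247,2,190,3,1.77,0.95,1.30
A8,315,1,258,2,243,4,192,3,1.22,1.06,1.27
A9,339,1,250,2,201,4,172,3,1.35,1.25,1.16
A10,451,4,203,3,199,2,191,1,2.22,1.02,1.04
B1,311,1,291,4,248,2,206,3,1.07,1.17,1.21
B3,349,4,292,1,243,3,237,2,1.19,1.20,1.03
C1,339,1,247,2,169,4,139,3,1.37,1.46,1.21
C2,374,4,276,1,247,3,233,2,1.35,1.12,1.06
D4,409,4,329,1,227,3,183,2,1.24,1.45,1.24
D5,342,1,342,3,238,4,223,2,1.00,1.44,1.07
E1,447,1,252,2,134,4,100,3,1.78,1.88,1.35
E2,386,4,339,1,232,3,202,2,1.14,1.46,1.15
E3,368,4,347,1,243,3,214,2,1.06,1.43,1.13
S2,313,4,302,1,246,2,210,3,1.04,1.23,1.17
S2H,368,4,284,1,244,3,234,2,1.29,1.17,1.04
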