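model,O5_MHz,W1_MHz,W2_MHz
A4,,3.8,16.7
A5,,0.7,0.6
A8,,1.2,3.9
A9,,0.9,0.4
A10,,8.2,0.5
B1,8.1,,4.7
B3,10.8,,1.4
C1,11.9,8.8,
C2,12.2,3.4,
D4,8.2,16.8,12.3
D5,33.9,3.6,0.9
E1,4.8,5.5,5.4
E2,8.6,2.4,11.1
E3,11.5,2.6,1.7
S2,8.5,9.4,1.3
S2H,12.0,1.2,2.5
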