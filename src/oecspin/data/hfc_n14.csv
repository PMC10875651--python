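model,nhx_aiso_MHz,nhx_eta,his332_aiso_MHz,his332_eta
A4,3.1,0.8,3.4,0.9
A5,6.4,0.9,2.5,0.6
A8,3.6,1.0,5.2,0.5
A9,3.6,1.0,5.6,0.6
A10,2.3,0.8,3.5,0.8
B1,3.0,0.8,5.4,0.7
B3,3.5,0.9,5.2,0.8
C1,1.2,0.3,5.9,0.7
C2,3.7,0.3,4.9,0.8
D4,4.6,0.9,1.0,0.6
D5,2.0,0.7,3.6,0.7
E1,13.7,0.3,1.2,0.5
E2,3.2,0.7,10.2,0.2
E3,10.6,0.2,1.1,0.6
S2,,,5.4,0.7
S2H,,,5.1,0.8
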