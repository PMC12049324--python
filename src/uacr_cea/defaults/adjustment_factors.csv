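g,a,factor
G1,A1,1
G1,A2,0.45
G1,A3,0.42
G2,A1,1
G2,A2,1.14
G2,A3,0.90
G3a,A1,1.21
G3a,A2,1.26
G3a,A3,0.9
G3b,A1,0.99
G3b,A2,0.63
G3b,A3,1.2
G4,A1,0.40
G4,A2,1
G4,A3,1.5
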