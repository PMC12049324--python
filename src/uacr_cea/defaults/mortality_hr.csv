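g,a,hr
G1,A1,1.140
G1,A2,1.880
G1,A3,4.010
G2,A1,1.140
G2,A2,1.790
G2,A3,2.130
G3a,A1,1.710
G3a,A2,2.390
G3a,A3,2.570
G3b,A1,2.590
G3b,A2,3.820
G3b,A3,4.030
G4,A1,4.710
G4,A2,4.410
G4,A3,5.860
G5,A1,4.850
G5,A2,12.000
G5,A3,8.690
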