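state,utility
LOW,0.940
MODERATE,0.913
HIGH,0.900
VERY_HIGH,0.859
ESKD,0.789
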