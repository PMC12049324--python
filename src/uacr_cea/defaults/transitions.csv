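from_state,to_state,probability
LOW,MODERATE,0.085
LOW,HIGH,0.002
LOW,VERY_HIGH,0.000
LOW,ESKD,0.000
MODERATE,LOW,0.337
MODERATE,HIGH,0.067
MODERATE,VERY_HIGH,0.000
MODERATE,ESKD,0.000
HIGH,LOW,0.067
HIGH,MODERATE,0.267
HIGH,VERY_HIGH,0.067
HIGH,ESKD,0.000
VERY_HIGH,LOW,0.000
VERY_HIGH,MODERATE,0.010
VERY_HIGH,HIGH,0.040
VERY_HIGH,ESKD,0.100
ESKD,LOW,0.000
ESKD,MODERATE,0.000
ESKD,HIGH,0.000
ESKD,VERY_HIGH,0.000
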