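parameter,value
reference_10yr_risk,0.109
hr_LOW,1.00
hr_MODERATE,1.52
hr_HIGH,2.04
hr_VERY_HIGH,3.69
hr_ESKD,12.00
mix_mi,0.09
mix_stroke_ischemic,0.63
mix_stroke_ich,0.15
mix_stroke_sah,0.06
mix_other_cv,0.07
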