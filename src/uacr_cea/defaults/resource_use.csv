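state,category,annual_count
LOW,gp_appointments,1
MODERATE,gp_appointments,12
HIGH,gp_appointments,12
VERY_HIGH,gp_appointments,0
ESKD,gp_appointments,0
LOW,nephrologist_appointments,0
MODERATE,nephrologist_appointments,2
HIGH,nephrologist_appointments,4
VERY_HIGH,nephrologist_appointments,12
ESKD,nephrologist_appointments,0
LOW,egfr_tests,1
MODERATE,egfr_tests,4
HIGH,egfr_tests,8
VERY_HIGH,egfr_tests,4
ESKD,egfr_tests,4
LOW,urine_tests,1
MODERATE,urine_tests,2
HIGH,urine_tests,4
VERY_HIGH,urine_tests,4
ESKD,urine_tests,4
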