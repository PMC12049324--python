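category,yen
drug_acei_arb,4015.00
drug_sglt2i,96725.00
dialysis_annual,5456714.14
gp_consultation,730.00
gp_tests_LOW,2870.00
gp_tests_MODERATE,480.00
gp_tests_HIGH,960.00
gp_tests_VERY_HIGH,0.00
gp_prescription_LOW,0.00
gp_prescription_MODERATE,3180.00
gp_prescription_HIGH,0.00
gp_prescription_VERY_HIGH,0.00
nephrologist_consultation,740.00
nephrologist_tests_LOW,0.00
nephrologist_tests_MODERATE,5370.00
nephrologist_tests_HIGH,11460.00
nephrologist_tests_VERY_HIGH,12670.00
nephrologist_prescription_LOW,0.00
nephrologist_prescription_MODERATE,0.00
nephrologist_prescription_HIGH,30680.00
nephrologist_prescription_VERY_HIGH,24740.00
other_nephrologist_LOW,0.00
other_nephrologist_MODERATE,2000.00
other_nephrologist_HIGH,2000.00
other_nephrologist_VERY_HIGH,10000.00
test_egfr,110.00
test_uacr,1730.00
test_upcr,810.00
event_vascular_access,1579488.00
event_mi,3090988.00
event_stroke_ischemic,2491671.00
event_stroke_ich,5156209.00
event_other_cv,2214259.00
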