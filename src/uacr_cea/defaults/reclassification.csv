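stratum,strategy,class,proportion,count
UNSTRATIFIED,UACR,A1,0.830,1027
UNSTRATIFIED,UACR,A2,0.160,198
UNSTRATIFIED,UACR,A3,0.011,13
UNSTRATIFIED,UPCR,A1,0.929,1150
UNSTRATIFIED,UPCR,A2,0.061,75
UNSTRATIFIED,UPCR,A3,0.011,13
DIPSTICK_NEGATIVE,UACR,A1,0.892,989
DIPSTICK_NEGATIVE,UACR,A2,0.108,120
DIPSTICK_NEGATIVE,UACR,A3,0.000,0
DIPSTICK_NEGATIVE,UPCR,A1,0.956,1060
DIPSTICK_NEGATIVE,UPCR,A2,0.044,49
DIPSTICK_NEGATIVE,UPCR,A3,0.000,0
DIPSTICK_TRACE,UACR,A1,0.406,28
DIPSTICK_TRACE,UACR,A2,0.594,41
DIPSTICK_TRACE,UACR,A3,0.000,0
DIPSTICK_TRACE,UPCR,A1,0.812,56
DIPSTICK_TRACE,UPCR,A2,0.188,13
DIPSTICK_TRACE,UPCR,A3,0.000,0
DIPSTICK_POSITIVE,UACR,A1,0.167,10
DIPSTICK_POSITIVE,UACR,A2,0.617,37
DIPSTICK_POSITIVE,UACR,A3,0.217,13
DIPSTICK_POSITIVE,UPCR,A1,0.567,34
DIPSTICK_POSITIVE,UPCR,A2,0.267,16
DIPSTICK_POSITIVE,UPCR,A3,0.167,10
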