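age,qx
40,0.00058780
41,0.00063592
42,0.00069002
43,0.00075083
44,0.00081918
45,0.00089601
46,0.00098236
47,0.00107943
48,0.00118853
49,0.00131116
50,0.00144899
51,0.00160391
52,0.00177803
53,0.00197372
54,0.00219366
55,0.00244083
56,0.00271862
57,0.00303079
58,0.00338158
59,0.00377578
60,0.00421871
61,0.00471638
62,0.00527553
63,0.00590370
64,0.00660937
65,0.00740203
66,0.00829232
67,0.00929216
68,0.01041489
69,0.01167545
70,0.01309056
71,0.01467890
72,0.01646132
73,0.01846113
74,0.02070430
75,0.02321977
76,0.02603975
77,0.02920002
78,0.03274030
79,0.03670459
80,0.04114153
81,0.04610479
82,0.05165342
83,0.05785221
84,0.06477204
85,0.07249009
86,0.08109009
87,0.09066234
88,0.10130371
89,0.11311728
90,0.12621184
91,0.14070100
92,0.15670192
93,0.17433341
94,0.19371359
95,0.21495666
96,0.23816895
97,0.26344392
98,0.29085628
99,0.32045493
100,0.35225500
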