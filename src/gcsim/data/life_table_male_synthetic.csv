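age,annual_qx
40,0.0016557725979346157
41,0.0018071801936923458
42,0.0019724328428600262
43,0.002152796568472795
44,0.0023496531615789635
45,0.002564510767329284
46,0.0027990154390822052
47,0.003054963749042666
48,0.003334316552046255
49,0.003639214007934981
50,0.003971991977613067
51,0.0043351999183952415
52,0.004731620415746204
53,0.0051642905010465335
54,0.005636524918703457
55,0.006151941520858828
56,0.006714488984246771
57,0.007328477061543552
58,0.00799860959896932
59,0.008730020573094207
60,0.0095283134229315
61,0.010399603978646524
62,0.011350567315763897
63,0.012388488893829496
64,0.013521320371307627
65,0.014757740524318616
66,0.016107221735923813
67,0.017580102565341423
68,0.019187666953055578
69,0.02094223066862018
70,0.022857235663445444
71,0.02494735305141708
72,0.02722859550629645
73,0.029718439936993357
74,0.032435961380543894
75,0.03540197913856497
76,0.03863921627675747
77,0.04217247370940514
78,0.04602882020255397
79,0.05023779975151301
80,0.05483165792142293
81,0.05984558888491912
82,0.06531800504947809
83,0.07129083134009849
84,0.07780982639185767
85,0.08492493311304203
86,0.09269066130456485
87,0.10116650526696896
88,0.11041739959436034
89,0.12051421664717096
90,0.13153430951495668
91,0.14356210462894445
92,0.156689748564411
93,0.17101781398813756
94,0.18665607015929642
95,0.20372432388668502
96,0.2223533373849925
97,0.24268583006192396
98,0.2648775719110037
99,0.28909857688669677
100,0.3155344054044512
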