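# Synthetic cohort life table (other-cause mortality, Gompertz-Makeham shape).
# Generated by crcscreen.population.make_default_life_table_arrays; stands in
# for a 1975-birth-cohort all-cause-minus-CRC table, which is not packaged.
age,qx
0,0.008427
1,0.00082969
2,0.00083265
3,0.0008359
4,0.00083948
5,0.00044342
6,0.00044774
7,0.0004525
8,0.00045773
9,0.00046349
10,0.00046981
11,0.00047677
12,0.00048442
13,0.00049284
14,0.00050209
15,0.00051226
16,0.00052345
17,0.00053575
18,0.00054928
19,0.00056416
20,0.00058052
21,0.00059851
22,0.00061829
23,0.00064005
24,0.00066397
25,0.00069028
26,0.00071921
27,0.00075102
28,0.000786
29,0.00082447
30,0.00086677
31,0.00091329
32,0.00096444
33,0.00102069
34,0.00108255
35,0.00115057
36,0.00122537
37,0.00130763
38,0.00139808
39,0.00149755
40,0.00160693
41,0.00172721
42,0.00185948
43,0.00200493
44,0.00216488
45,0.00234076
46,0.00253418
47,0.00274687
48,0.00298075
49,0.00323795
50,0.00352078
51,0.00383179
52,0.0041738
53,0.00454989
54,0.00496346
55,0.00541825
56,0.00591836
57,0.00646832
58,0.00707308
59,0.00773811
60,0.00846942
61,0.00927361
62,0.01015794
63,0.01113041
64,0.01219979
65,0.01337574
66,0.01466889
67,0.01609091
68,0.01765465
69,0.01937423
70,0.02126518
71,0.02334458
72,0.02563121
73,0.02814572
74,0.03091083
75,0.0339515
76,0.0372952
77,0.04097214
78,0.04501551
79,0.04946184
80,0.05435129
81,0.05972801
82,0.06564057
83,0.07214238
84,0.07929214
85,0.08715444
86,0.09580029
87,0.10530777
88,0.11576276
89,0.12725968
90,0.13990237
91,0.15380502
92,0.16909318
93,0.18590495
94,0.20439217
95,0.22472179
96,0.24707744
97,0.27166104
98,0.2986946
99,0.3284223
100,0.36111262
101,0.39706083
102,0.4365916
103,0.48006195
104,0.52786451
105,0.58043102
106,0.63823625
107,0.70180228
108,0.77170323
109,0.84857042
110,1.0
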