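sample_id,measured,estimated
1,0.393,0.433
2,0.244,0.215
3,0.328,0.319
4,0.122,0.096
5,0.259,0.272
6,0.486,0.562
7,0.319,0.290
8,0.165,0.174
9,0.173,0.201
10,0.298,0.269
11,0.389,0.416
12,0.235,0.284
13,0.225,0.222
14,0.102,0.131
15,0.105,0.141
16,0.152,0.163
17,0.403,0.340
18,0.144,0.154
19,0.108,0.124
20,0.273,0.267
21,0.388,0.404
22,0.371,0.387
23,0.456,0.480
24,0.264,0.247
25,0.348,0.330
26,0.257,0.240
27,0.170,0.136
28,0.184,0.149
29,0.353,0.337
30,0.351,0.343
31,0.296,0.255
32,0.356,0.342
33,0.214,0.233
34,0.215,0.277
35,0.172,0.150
36,0.163,0.146
37,0.067,0.077
38,0.075,0.077
39,0.117,0.127
40,0.253,0.242
41,0.381,0.418
42,0.145,0.125
43,0.268,0.259
44,0.272,0.247
45,0.060,0.046
46,0.298,0.323
47,0.192,0.168
48,0.209,0.209
49,0.361,0.343
50,0.112,0.150
51,0.233,0.193
52,0.226,0.215
53,0.253,0.281
54,0.299,0.271
55,0.056,0.071
56,0.138,0.168
57,0.141,0.167
58,0.109,0.106
59,0.201,0.207
60,0.385,0.425
61,0.314,0.289
62,0.120,0.130
63,0.227,0.201
64,0.125,0.120
65,0.416,0.451
66,0.160,0.195
67,0.281,0.278
68,0.162,0.186
69,0.322,0.277
70,0.195,0.231
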