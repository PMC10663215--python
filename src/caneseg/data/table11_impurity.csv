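sample_id,measured,estimated
1,0.473,0.499
2,0.237,0.254
3,0.423,0.424
4,0.292,0.298
5,0.303,0.263
6,0.602,0.570
7,0.445,0.445
8,0.372,0.341
9,0.393,0.352
10,0.294,0.280
11,0.529,0.554
12,0.277,0.272
13,0.378,0.388
14,0.206,0.199
15,0.332,0.314
16,0.240,0.217
17,0.482,0.452
18,0.277,0.298
19,0.331,0.317
20,0.274,0.265
21,0.358,0.322
22,0.491,0.470
23,0.417,0.439
24,0.286,0.318
25,0.273,0.241
26,0.316,0.337
27,0.267,0.265
28,0.251,0.272
29,0.208,0.249
30,0.375,0.334
31,0.296,0.347
32,0.229,0.290
33,0.283,0.279
34,0.357,0.332
35,0.350,0.342
36,0.328,0.319
37,0.313,0.322
38,0.091,0.104
39,0.217,0.240
40,0.380,0.381
41,0.241,0.240
42,0.369,0.369
43,0.292,0.282
44,0.328,0.337
45,0.146,0.167
46,0.274,0.316
47,0.310,0.273
48,0.410,0.382
49,0.254,0.269
50,0.320,0.319
51,0.343,0.386
52,0.328,0.325
53,0.385,0.355
54,0.211,0.232
55,0.228,0.248
56,0.420,0.389
57,0.268,0.267
58,0.209,0.200
59,0.239,0.245
60,0.427,0.421
61,0.332,0.320
62,0.319,0.315
63,0.253,0.239
64,0.313,0.339
65,0.500,0.483
66,0.418,0.378
67,0.297,0.320
68,0.299,0.337
69,0.475,0.465
70,0.301,0.302
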