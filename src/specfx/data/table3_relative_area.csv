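peak,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10,rsd_printed
1,0.911,0.606,1.377,2.029,2.516,1.359,1.423,3.001,1.787,1.323,44.213
2,0.363,0.224,0.658,1.012,0.820,0.642,0.851,1.628,0.971,0.656,49.425
3,0.313,0.224,0.524,0.972,0.788,0.442,0.557,1.114,0.726,0.517,45.793
4,0.388,0.158,0.489,0.503,0.991,0.624,0.844,1.744,0.933,0.710,59.214
5,0.863,0.394,1.014,1.112,1.476,1.157,1.642,3.436,2.248,1.136,58.978
6,1.669,0.571,1.487,2.552,2.148,1.304,0.702,2.220,2.083,1.167,41.824
7,0.984,0.480,0.743,1.503,1.501,0.831,0.756,1.375,1.075,0.731,35.772
8,0.307,0.190,0.400,0.555,0.717,0.303,0.450,0.766,0.486,0.374,40.220
9,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,0.000
10,0.435,0.215,0.312,0.790,0.763,0.322,0.444,0.911,0.560,0.361,46.184
11,1.497,1.301,1.214,1.819,1.129,1.009,0.939,1.048,1.081,0.892,28.412
12,0.232,0.148,0.414,0.696,0.447,0.247,0.291,0.554,0.419,0.278,44.504
13,0.236,0.136,0.142,0.219,0.281,0.205,0.524,0.363,0.182,0.159,48.980
14,0.303,0.178,0.183,0.495,0.320,0.201,0.356,0.386,0.234,0.169,38.163
15,0.019,0.010,0.033,0.061,0.027,0.049,0.065,0.140,0.097,0.052,70.909
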