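peak,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10,rsd_printed
1,0.103,0.103,0.103,0.103,0.103,0.103,0.103,0.103,0.103,0.103,0.000
2,0.163,0.164,0.164,0.164,0.164,0.164,0.164,0.164,0.164,0.165,0.000
3,0.344,0.348,0.352,0.342,0.346,0.345,0.348,0.345,0.345,0.346,0.867
4,0.516,0.517,0.517,0.516,0.516,0.516,0.517,0.517,0.517,0.518,0.193
5,0.579,0.579,0.580,0.578,0.579,0.579,0.580,0.579,0.579,0.580,0.172
6,0.710,0.710,0.710,0.708,0.708,0.709,0.710,0.709,0.709,0.709,0.141
7,0.839,0.837,0.837,0.837,0.837,0.838,0.837,0.838,0.837,0.837,0.119
8,0.865,0.865,0.865,0.865,0.865,0.865,0.865,0.865,0.865,0.866,0.000
9,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,0.000
10,1.036,1.036,1.036,1.037,1.037,1.036,1.036,1.036,1.036,1.036,0.000
11,1.084,1.084,1.084,1.085,1.085,1.084,1.084,1.084,1.085,1.084,0.000
12,1.307,1.308,1.306,1.306,1.307,1.306,1.308,1.307,1.307,1.307,0.077
13,1.442,1.439,1.438,1.442,1.442,1.440,1.442,1.441,1.442,1.443,0.069
14,1.484,1.481,1.481,1.486,1.485,1.483,1.485,1.483,1.485,1.486,0.135
15,1.575,1.573,1.573,1.579,1.578,1.576,1.577,1.575,1.578,1.579,0.127
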