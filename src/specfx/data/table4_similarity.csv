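batch,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10,Control
S1,1,,,,,,,,,,
S2,0.930,1,,,,,,,,,
S3,0.967,0.901,1,,,,,,,,
S4,0.965,0.865,0.979,1,,,,,,,
S5,0.919,0.805,0.969,0.967,1,,,,,,
S6,0.954,0.882,0.991,0.961,0.977,1,,,,,
S7,0.860,0.821,0.927,0.874,0.925,0.957,1,,,,
S8,0.833,0.710,0.917,0.883,0.949,0.947,0.963,1,,,
S9,0.914,0.791,0.964,0.937,0.965,0.979,0.950,0.98,1,,
S10,0.935,0.868,0.986,0.950,0.976,0.997,0.967,0.957,0.979,1,
Control,0.962,0.894,0.993,0.968,0.975,0.998,0.957,0.942,0.977,0.995,1
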