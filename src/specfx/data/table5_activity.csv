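batch_id,dpph_pct,t_aoc,sd_taoc
S1,69.69,1.74,0.06
S2,79.01,1.26,0.06
S3,53.34,1.45,0.05
S4,70.27,1.18,0.05
S5,65.41,0.94,0.06
S6,75.48,0.95,0.05
S7,82.49,1.22,0.05
S8,54.91,1.10,0.06
S9,82.21,1.13,0.06
S10,82.39,1.75,0.06
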