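peak,dpph_degree,dpph_rank,taoc_degree,taoc_rank
1,0.812,5,0.791,7
2,0.827,4,0.793,6
3,0.710,9,0.638,14
4,0.694,11,0.653,13
5,0.760,7,0.821,3
6,0.828,3,0.834,2
7,0.850,2,0.806,5
8,0.702,10,0.708,11
9,0.862,1,0.815,4
10,0.655,14,0.724,10
11,0.655,13,0.724,9
12,0.789,6,0.856,1
13,0.670,12,0.677,12
14,0.738,8,0.749,8
15,0.614,15,0.574,15
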