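patient,category,dose_gy,n_lesions
1,liver,5.79,7
2,liver,8.35,7
2,lymph_node,4.88,1
3,liver,44.82,21
3,visceral,3.24,7
3,pancreas,0.88,1
4,liver,10.27,2
4,lymph_node,2.49,4
5,liver,5.75,22
6,lymph_node,3.60,10
7,liver,9.56,9
7,lymph_node,2.14,1
8,liver,14.55,32
8,bone,6.32,1
9,liver,7.10,1
10,liver,2.48,5
11,liver,1.46,3
11,bone,1.48,1
12,liver,12.72,4
12,bone,6.95,1
13,liver,6.91,38
13,bone,6.93,1
13,pancreas,5.23,1
14,liver,7.07,4
14,bone,12.55,14
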