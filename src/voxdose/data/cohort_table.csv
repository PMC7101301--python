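patient,age_y,grade,cga_pre_ug_l,cga_post_ug_l,cga_interval_months,cycles,activity_mbq,kidney_dose_gy,spleen_dose_gy,ttd_gy
1,45,3,494,1026,5,4,6532,2.24,1.89,5.79
2,66,3,1121,706,4,4,6532,3.13,4.60,7.50
3,54,1,661,1956,4,2,6532,4.71,10.04,39.49
4,67,2,1352,1473,6,3,6532,2.58,2.69,8.88
5,78,2,34,31,4,3,6532,3.55,3.04,5.75
6,54,2,54,77,4,3,6532,2.90,2.81,3.60
7,67,2,597,1748,2,2,6532,3.76,1.14,9.48
8,54,2,1319,682,4,4,6532,2.55,3.51,14.48
9,77,2,2242,46,1,1,6532,6.22,6.01,7.10
10,52,3,46,83,5,2,6532,3.07,2.88,2.48
11,52,3,76,47,4,3,6532,2.53,2.02,1.47
12,71,2,51,51,3,2,6532,2.71,3.68,11.17
13,49,3,139,214,2,2,6532,1.91,6.13,6.91
14,79,2,289,2413,7,4,6532,5.93,11.22,11.73
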