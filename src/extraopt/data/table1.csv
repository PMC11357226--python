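run,x1_actual,x2_actual,x3_actual,x4_actual,response,rsm_predicted,ann_predicted
1,40,70,25,90,80.05,80.12,84.78
2,80,70,25,90,87.39,81.54,88.02
3,40,90,25,90,72.95,71.99,72.95
4,80,90,25,90,84.64,77.75,84.23
5,60,80,20,60,89.92,79.11,90.23
6,60,80,30,60,71.11,72.19,72.68
7,60,80,20,120,67.61,59.72,69.7
8,60,80,30,120,114.69,118.69,114.82
9,40,80,25,60,78.68,76.96,78.92
10,80,80,25,60,69.51,70.46,72.41
11,40,80,25,120,78.68,80.42,81.99
12,80,80,25,120,89.69,94.1,92.77
13,60,70,20,90,59.01,68.56,59.54
14,60,90,20,90,63.82,65.0,63.82
15,60,70,30,90,95.48,96.99,94.54
16,60,90,30,90,95.48,88.62,100.85
17,40,80,20,90,56.09,58.45,58.75
18,80,80,20,90,55.91,61.52,56.74
19,40,80,30,90,85.45,83.96,85.66
20,80,80,30,90,86.31,88.07,87.78
21,60,70,25,60,82.81,83.36,83.89
22,60,90,25,60,67.67,77.63,69.01
23,60,70,25,120,102.99,97.15,106.77
24,60,90,25,120,87.39,90.96,87.54
25,60,80,25,90,125.46,121.52,123.39
26,60,80,25,90,123.4,121.52,123.39
27,60,80,25,90,118.58,121.52,123.39
28,60,80,25,90,116.52,121.52,123.39
29,60,80,25,90,123.63,121.52,123.39
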