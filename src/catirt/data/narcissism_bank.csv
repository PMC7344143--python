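item_id,model,a,b1,b2,b3,b4,ctt_threshold,ctt_discrimination,s_chi2_p
1,GRM,0.818,2.436,,,,0.15,0.30,0.937
2,GRM,0.705,1.784,,,,0.24,0.29,0.934
3,GRM,0.986,2.265,,,,0.13,0.30,0.212
4,GRM,1.249,2.187,,,,0.10,0.32,0.072
5,GRM,1.158,1.899,,,,0.14,0.37,0.244
6,GRM,0.900,0.721,,,,0.37,0.38,0.149
7,GRM,1.199,1.818,,,,0.15,0.38,0.669
8,GRM,1.156,1.453,,,,0.21,0.41,0.298
9,GRM,1.325,1.660,,,,0.16,0.41,0.012
10,GRM,0.871,1.538,,,,0.24,0.34,0.307
11,GRM,1.634,1.676,,,,0.13,0.44,0.212
12,GRM,1.706,1.676,,,,0.12,0.44,0.118
13,GRM,2.020,1.538,,,,0.12,0.48,0.871
14,GRM,0.942,2.077,,,,0.16,0.33,0.542
15,GRM,0.704,-0.010,,,,0.50,0.32,0.021
16,GRM,0.688,1.031,,,,0.35,0.32,0.576
17,GRM,1.200,0.306,,,,0.43,0.47,0.275
18,GRM,1.958,1.483,,,,0.14,0.49,0.208
19,GRM,2.191,1.587,,,,0.11,0.48,0.455
20,GRM,1.031,1.363,,,,0.24,0.39,0.691
21,GRM,1.328,1.623,,,,0.16,0.42,0.680
22,GRM,1.418,1.532,,,,0.17,0.44,0.796
23,GRM,1.738,1.475,,,,0.15,0.48,0.034
24,GRM,1.258,1.610,,,,0.17,0.41,0.132
25,GRM,2.062,1.564,,,,0.12,0.48,0.031
26,GRM,1.959,1.453,,,,0.14,0.50,0.335
27,GRM,0.779,1.646,,,,0.24,0.33,0.903
28,GRM,0.927,0.876,,,,0.34,0.39,0.494
29,GRM,1.067,0.861,,,,0.32,0.42,0.525
30,GRM,0.656,0.596,,,,0.41,0.31,0.207
31,GRM,1.003,0.523,,,,0.39,0.42,0.282
32,GRM,2.146,1.599,,,,0.11,0.47,0.104
33,GRM,0.885,1.425,,,,0.25,0.36,0.908
34,GRM,1.618,1.075,,,,0.23,0.51,0.591
35,GRM,1.313,1.408,,,,0.20,0.43,0.367
36,GRM,1.123,1.305,,,,0.24,0.41,0.807
37,GRM,2.438,1.284,,,,0.15,0.56,0.323
38,GRM,2.257,1.557,,,,0.11,0.50,0.867
39,GRM,1.946,1.581,,,,0.12,0.48,0.131
40,GRM,1.422,1.118,,,,0.24,0.49,0.173
41,GRM,1.184,1.145,,,,0.26,0.43,0.991
42,GRM,0.799,0.651,,,,0.39,0.35,0.617
43,GRM,1.477,1.386,,,,0.18,0.45,0.576
44,GRM,1.378,1.404,,,,0.19,0.44,0.320
45,GRM,0.667,-0.246,,,,0.54,0.30,0.186
46,GRM,0.642,0.726,,,,0.40,0.30,0.436
47,GRM,1.753,1.463,,,,0.15,0.48,0.138
48,GRM,0.914,1.652,,,,0.22,0.36,0.291
49,GRM,2.170,1.535,,,,0.12,0.49,0.421
50,GRM,0.809,0.564,,,,0.40,0.36,0.737
51,GRM,1.755,1.338,,,,0.17,0.50,0.175
52,GRM,2.385,1.677,,,,0.09,0.46,0.075
53,GRM,1.369,1.318,,,,0.21,0.45,0.413
54,GRM,2.070,1.505,,,,0.13,0.50,0.555
55,GRM,1.491,1.076,,,,0.24,0.50,0.682
56,GRM,0.843,0.308,,,,0.45,0.36,0.104
57,GRM,1.595,1.451,,,,0.16,0.47,0.117
58,GRM,1.244,1.207,,,,0.24,0.44,0.527
59,GRM,0.784,0.855,,,,0.36,0.34,0.945
60,GRM,1.441,1.588,,,,0.15,0.42,0.324
61,GRM,1.225,1.018,,,,0.28,0.45,0.319
62,GRM,1.626,1.370,,,,0.18,0.48,0.357
63,GRM,2.016,1.558,,,,0.12,0.48,0.325
64,GRM,0.701,0.873,,,,0.37,0.33,0.354
65,GRM,1.305,0.986,,,,0.28,0.47,0.015
66,GRM,0.797,2.304,,,,0.16,0.28,0.355
67,GRM,1.532,1.463,,,,0.17,0.46,0.908
68,GRM,1.733,1.728,,,,0.11,0.43,0.212
69,GRM,0.954,-2.318,-0.611,0.708,3.266,0.38,0.50,0.457
70,GRM,0.926,-3.188,-1.033,0.419,2.946,0.43,0.46,0.037
71,GRM,1.613,-0.659,0.595,1.400,2.542,0.24,0.65,0.477
72,GRM,1.715,-1.091,0.327,1.731,2.929,0.26,0.67,0.088
73,GRM,0.820,-2.772,-0.028,1.859,4.449,0.33,0.42,0.157
74,GRM,1.072,-2.121,-0.471,0.597,2.591,0.39,0.51,0.162
75,GRM,1.296,-2.093,-0.272,1.160,2.908,0.35,0.56,0.112
76,GRM,1.752,-0.900,0.572,1.362,2.759,0.26,0.67,0.175
77,GRM,1.416,-1.000,0.427,1.570,2.973,0.27,0.60,0.327
78,GRM,0.939,-1.967,0.639,2.141,4.122,0.28,0.49,0.584
79,GRM,0.700,-5.449,-2.013,1.551,5.146,0.41,0.37,0.688
80,GRM,1.005,-2.539,-0.113,1.484,3.624,0.34,0.50,0.524
81,GRM,0.868,-1.364,1.105,2.289,4.457,0.24,0.46,0.195
82,GRM,0.813,-3.704,-0.876,0.632,4.102,0.41,0.42,0.192
83,GRM,2.021,-0.919,0.673,1.511,2.688,0.24,0.71,0.670
84,GRM,1.743,-1.270,0.308,1.300,2.614,0.29,0.67,0.697
85,GRM,0.611,-5.404,-2.077,0.015,3.964,0.46,0.34,0.017
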