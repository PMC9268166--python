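compound,CHI_IAM,logk_IAM,CHI_C18,CHI_logD,logkw_C8,logkw_CN,logkw_Ph,pKa,pIC50
1,19.20,1.28,56.70,1.51,2.98,1.58,2.62,6.6,4.34
2,45.00,2.45,97.50,3.65,4.68,4.04,6.22,7.3,6.00
3,42.00,2.31,94.80,3.51,4.59,2.97,5.56,7.4,4.72
4,45.90,2.49,104.80,4.04,4.90,3.63,7.39,7.3,5.05
5,31.40,1.83,82.90,2.89,4.06,2.30,4.08,6.5,4.64
6,45.40,2.46,94.70,3.50,4.61,2.89,5.39,7.8,4.15
7,24.30,1.51,63.80,1.88,3.30,1.78,2.81,6.9,4.16
8,36.70,2.07,82.80,2.88,4.21,2.01,4.49,5.5,4.10
9,31.40,1.83,72.30,2.33,3.69,1.85,2.88,5.4,4.07
10,39.10,2.18,84.30,2.96,4.21,2.25,4.19,5.5,4.05
11,35.50,2.02,80.30,2.75,4.07,2.13,3.82,5.5,4.06
12,35.20,2.00,79.30,2.70,4.07,2.16,3.90,5.4,4.06
13,37.10,2.09,77.90,2.62,4.03,2.04,3.53,5.7,4.12
14,35.80,2.03,78.90,2.68,4.13,2.02,4.31,5.1,4.11
15,43.40,2.37,92.50,3.39,4.53,2.64,5.07,5.1,4.19
16,39.80,2.21,85.90,3.04,4.38,2.47,4.48,5.1,4.12
17,41.40,2.28,89.90,3.25,4.49,2.54,4.54,5.1,4.15
18,37.50,2.11,82.80,2.88,4.28,2.36,4.23,5.1,4.12
19,33.60,1.93,79.70,2.72,4.07,2.22,3.97,5.0,4.12
20,34.90,1.99,77.20,2.59,4.02,2.21,3.79,5.1,4.14
21,41.30,2.28,91.60,3.34,4.44,2.11,4.48,5.7,4.29
22,42.20,2.32,84.60,2.97,4.28,2.36,4.25,5.7,4.31
23,41.10,2.27,86.10,3.05,4.12,2.48,4.40,5.8,4.42
24,38.30,2.14,87.50,3.13,4.26,2.28,4.09,5.7,4.17
25,37.20,2.09,84.40,2.96,4.26,2.33,3.89,5.7,4.17
26,30.60,1.80,84.10,2.95,3.66,1.76,2.87,5.2,4.85
27,39.60,2.20,73.10,2.37,4.28,2.31,4.46,4.6,4.11
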