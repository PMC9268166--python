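compound,iLogP,XLogP3,WLogP,MLogP,Silicos-IT LogP,Consensus LogP,KOWWIN LogP
1,2.12,1.22,3.27,0.58,0.97,1.63,1.78
2,2.59,2.15,4.72,2.04,2.02,2.70,4.23
3,2.82,3.48,5.02,2.27,2.53,3.23,4.78
4,2.95,3.51,5.02,2.27,2.53,3.26,4.78
5,2.41,2.71,4.17,1.23,2.11,2.53,3.44
6,2.52,3.79,4.82,2.58,2.20,3.18,3.93
7,2.74,1.36,3.57,0.83,1.47,2.00,2.32
8,2.56,5.82,7.80,3.93,5.83,5.19,7.38
9,2.05,4.53,5.42,3.24,4.72,3.99,6.38
10,2.35,6.19,6.78,4.06,5.74,5.03,7.59
11,2.68,5.31,5.93,3.68,5.62,4.64,7.61
12,2.13,5.14,5.84,2.88,3.49,3.89,5.23
13,3.29,4.81,6.89,3.85,5.01,4.77,5.02
14,3.18,5.15,7.09,3.44,4.85,4.74,5.06
15,3.71,6.69,9.91,4.68,6.53,6.30,6.58
16,4.15,5.78,7.75,3.90,5.50,5.42,5.70
17,3.78,6.43,9.56,4.42,6.42,6.12,6.49
18,4.10,5.52,7.40,3.63,5.39,5.21,5.61
19,4.28,5.46,7.42,3.00,5.57,5.15,5.04
20,3.43,5.12,7.10,3.13,4.94,4.74,5.14
21,3.37,6.48,10.67,4.75,6.79,6.41,6.74
22,4.04,6.06,8.04,4.48,6.02,5.73,6.19
23,3.30,5.93,7.49,3.78,5.67,5.24,6.07
24,3.58,5.70,9.06,4.36,6.11,5.76,5.98
25,3.70,5.57,8.51,3.66,5.76,5.44,5.86
26,2.39,4.92,5.85,3.55,4.61,4.27,4.99
27,3.18,7.00,7.43,4.73,6.31,5.73,6.97
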