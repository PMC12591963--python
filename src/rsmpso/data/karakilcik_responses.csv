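run,x1,x2,taste_mean,taste_sd,taste_pred,color_mean,color_sd,color_pred,smell_mean,smell_sd,smell_pred,accept_mean,accept_sd,accept_pred
1,140,400,6.53,0.07,6.61,7.25,0.10,7.12,6.72,0.03,6.75,7.15,0.57,7.09
2,150,400,5.68,0.16,5.77,6.73,0.49,6.62,6.69,0.11,6.70,6.25,0.03,6.17
3,140,400,6.53,0.25,6.61,7.25,0.21,7.12,6.72,0.31,6.75,7.15,0.21,7.09
4,140,400,6.53,0.27,6.61,7.25,0.08,7.12,6.72,0.23,6.75,7.15,0.27,7.09
5,135,425,6.43,0.10,6.54,6.84,0.18,6.83,6.16,0.79,6.22,6.73,0.35,6.74
6,145,425,6.76,0.15,6.85,7.48,0.20,7.42,7.58,0.11,7.67,7.44,0.44,7.45
7,145,375,5.83,0.04,5.88,6.60,0.14,6.54,5.85,0.05,5.90,6.37,0.54,6.39
8,140,350,5.85,0.24,5.92,5.97,0.16,5.85,5.85,0.73,5.88,6.02,0.20,5.95
9,140,450,7.05,0.35,7.13,7.47,0.07,7.32,7.23,0.95,7.26,7.75,0.07,7.68
10,140,400,6.53,0.04,6.61,7.25,0.16,7.12,6.72,0.08,6.75,7.15,0.18,7.09
11,135,375,6.23,0.31,6.30,6.25,0.69,6.24,6.60,0.17,6.62,6.06,0.41,6.07
12,140,400,6.53,0.10,6.61,7.25,0.28,7.12,6.72,0.14,6.75,7.15,0.35,7.09
13,130,400,5.82,0.19,5.88,5.88,0.06,5.73,5.92,0.21,5.97,5.21,0.48,5.15
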