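run,x1,x2,taste_mean,taste_sd,taste_pred,color_mean,color_sd,color_pred,smell_mean,smell_sd,smell_pred,accept_mean,accept_sd,accept_pred
1,140,400,7.51,0.45,7.51,6.84,0.23,6.78,5.67,0.10,5.59,6.07,0.13,6.01
2,150,400,6.53,0.07,6.57,7.42,0.19,7.36,7.68,0.56,7.67,6.29,0.03,6.19
3,140,400,7.51,0.14,7.51,6.84,0.37,6.78,5.67,0.17,5.59,6.07,0.17,6.01
4,140,400,7.51,0.18,7.51,6.84,0.49,6.78,5.67,0.11,5.59,6.07,0.15,6.01
5,135,425,6.74,0.21,6.85,6.96,0.25,7.03,5.43,0.24,5.57,5.53,0.35,5.60
6,145,425,7.15,0.16,7.17,7.20,0.06,7.24,7.54,0.14,7.52,7.46,0.19,7.57
7,145,375,7.01,0.24,7.00,6.33,0.46,6.36,5.98,0.58,5.94,4.80,0.34,4.91
8,140,350,6.84,0.40,6.83,5.80,0.21,5.74,6.07,0.10,6.00,6.11,0.10,6.03
9,140,450,6.60,0.07,6.61,7.04,0.14,6.96,7.81,0.07,7.70,7.51,0.41,7.45
10,140,400,7.51,0.22,7.51,6.84,0.38,6.78,5.67,0.16,5.59,6.07,0.58,6.01
11,135,375,7.16,0.31,7.24,6.63,0.16,6.68,5.36,0.05,5.46,6.78,0.12,6.85
12,140,400,7.51,0.25,7.51,6.84,0.30,6.78,5.67,0.18,5.59,6.07,0.29,6.01
13,130,400,6.53,0.20,6.49,7.54,0.37,7.46,5.40,0.06,5.24,6.22,0.09,6.17
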