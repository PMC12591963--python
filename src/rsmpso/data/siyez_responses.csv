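run,x1,x2,taste_mean,taste_sd,taste_pred,color_mean,color_sd,color_pred,smell_mean,smell_sd,smell_pred,accept_mean,accept_sd,accept_pred
1,140,400,7.15,0.07,7.25,6.67,0.72,6.65,5.40,0.38,5.46,6.79,0.06,6.80
2,150,400,6.99,0.11,7.10,7.51,0.61,7.49,7.33,0.06,7.45,6.64,0.89,6.65
3,140,400,7.15,0.20,7.25,6.67,0.61,6.65,5.40,0.21,5.46,6.79,0.30,6.80
4,140,400,7.15,0.04,7.25,6.67,0.74,6.65,5.40,0.27,5.46,6.79,0.47,6.80
5,135,425,6.65,0.08,6.63,7.17,0.08,7.04,5.50,0.14,5.54,6.32,0.93,6.21
6,145,425,7.56,0.13,7.54,7.00,0.52,6.90,6.34,0.16,6.27,7.18,0.07,7.08
7,145,375,6.52,0.20,6.68,6.94,0.23,6.97,6.70,0.07,6.79,6.19,0.79,6.26
8,140,350,6.28,0.11,6.29,6.43,0.20,6.36,6.80,0.62,6.78,5.97,0.55,5.89
9,140,450,6.60,0.07,6.80,6.97,0.25,7.01,6.36,0.28,6.51,6.27,0.75,6.37
10,140,400,7.15,0.27,7.25,6.67,0.14,6.65,5.40,0.54,5.46,6.79,0.13,6.80
11,135,375,6.82,0.11,6.98,6.31,0.61,6.32,5.10,0.31,5.30,6.48,0.18,6.54
12,140,400,7.15,0.16,7.25,6.67,0.34,6.65,5.40,0.20,5.46,6.79,0.13,6.80
13,130,400,6.37,0.08,6.47,6.99,0.27,6.98,5.23,0.18,5.23,6.05,1.27,6.06
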