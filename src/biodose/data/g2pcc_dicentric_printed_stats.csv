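dose_gy,yield,se_yield,var_mean,se_var_mean,u
0.1,0.02,0.01,0.99,0.1,-0.1
0.25,0.05,0.02,0.95,0.11,-0.39
0.5,0.12,0.02,0.98,0.11,-0.1
0.75,0.18,0.02,1,0.08,0.05
1,0.38,0.04,1.12,0.09,1.3
2,0.7,0.06,1.05,0.1,0.48
3,1.35,0.1,0.93,0.13,-0.5
4,2.18,0.14,1.16,0.12,1.34
5,3.02,0.22,0.61,0.18,-2.11
7.5,5.68,0.39,0.59,0.23,-1.71
10,7.32,0.51,0.3,0.27,-2.56
15,9.64,0.62,0.57,0.28,-1.46
20,13.75,0.53,0.76,0.2,-1.15
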