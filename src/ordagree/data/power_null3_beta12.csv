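# ordagree power table (published reference grid, 10000 replicates)
# hypothesis: beta12
# null_or: 3
# margins: 0.2,0.2,0.2,0.2,0.2
beta,or,dd,p_50,p_100,p_150,p_200,p_250
0.00,1,0.00,0.34,0.57,0.74,0.85,0.92
0.69,2,0.50,0.10,0.12,0.16,0.19,0.21
1.10,3,0.67,0.07,0.06,0.06,0.05,0.05
1.39,4,0.75,0.08,0.08,0.10,0.11,0.12
1.61,5,0.80,0.11,0.14,0.17,0.21,0.26
1.79,6,0.83,0.15,0.20,0.27,0.35,0.42
1.95,7,0.86,0.18,0.27,0.38,0.46,0.55
2.08,8,0.87,0.22,0.34,0.45,0.56,0.67
2.20,9,0.88,0.24,0.39,0.54,0.66,0.76
2.30,10,0.90,0.28,0.43,0.60,0.73,0.82
2.48,12,0.92,0.33,0.53,0.70,0.83,0.89
2.64,14,0.93,0.38,0.61,0.78,0.89,0.95
2.77,16,0.94,0.42,0.67,0.83,0.92,0.97
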