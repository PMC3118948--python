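# ordagree power table (published reference grid, 10000 replicates)
# hypothesis: beta12_23
# null_or: 4
# margins: 0.2,0.2,0.2,0.2,0.2
beta,or,dd,p_50,p_100,p_150,p_200,p_250
0.00,1,0.00,0.85,0.99,1.00,1.00,1.00
0.69,2,0.50,0.23,0.43,0.60,0.67,0.76
1.10,3,0.67,0.09,0.12,0.13,0.15,0.18
1.39,4,0.75,0.05,0.05,0.05,0.06,0.05
1.61,5,0.80,0.07,0.08,0.11,0.10,0.10
1.79,6,0.83,0.11,0.11,0.15,0.21,0.22
1.95,7,0.86,0.14,0.18,0.25,0.28,0.35
2.08,8,0.87,0.14,0.22,0.31,0.40,0.45
2.20,9,0.88,0.17,0.29,0.41,0.50,0.57
2.30,10,0.90,0.23,0.33,0.49,0.56,0.69
2.48,12,0.92,0.25,0.41,0.59,0.73,0.81
2.64,14,0.93,0.29,0.51,0.67,0.79,0.86
2.77,16,0.94,0.30,0.56,0.75,0.86,0.92
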