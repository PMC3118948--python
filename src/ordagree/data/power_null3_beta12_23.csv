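# ordagree power table (published reference grid, 10000 replicates)
# hypothesis: beta12_23
# null_or: 3
# margins: 0.2,0.2,0.2,0.2,0.2
beta,or,dd,p_50,p_100,p_150,p_200,p_250
0.00,1,0.00,0.73,0.95,0.99,1.00,1.00
0.69,2,0.50,0.14,0.21,0.28,0.35,0.42
1.10,3,0.67,0.06,0.06,0.05,0.05,0.05
1.39,4,0.75,0.09,0.10,0.13,0.15,0.18
1.61,5,0.80,0.13,0.19,0.26,0.33,0.39
1.79,6,0.83,0.19,0.29,0.40,0.50,0.59
1.95,7,0.86,0.22,0.37,0.51,0.64,0.74
2.08,8,0.87,0.27,0.47,0.62,0.74,0.82
2.20,9,0.88,0.32,0.53,0.69,0.81,0.89
2.30,10,0.90,0.35,0.57,0.76,0.87,0.92
2.48,12,0.92,0.41,0.67,0.84,0.92,0.97
2.64,14,0.93,0.46,0.74,0.89,0.96,0.99
2.77,16,0.94,0.50,0.79,0.93,0.97,0.99
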