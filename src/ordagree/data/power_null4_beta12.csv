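# ordagree power table (published reference grid, 10000 replicates)
# hypothesis: beta12
# null_or: 4
# margins: 0.2,0.2,0.2,0.2,0.2
beta,or,dd,p_50,p_100,p_150,p_200,p_250
0.00,1,0.00,0.40,0.66,0.82,0.92,0.97
0.69,2,0.50,0.16,0.22,0.31,0.35,0.45
1.10,3,0.67,0.07,0.09,0.08,0.12,0.12
1.39,4,0.75,0.06,0.05,0.05,0.04,0.06
1.61,5,0.80,0.08,0.06,0.06,0.08,0.08
1.79,6,0.83,0.09,0.10,0.12,0.14,0.16
1.95,7,0.86,0.11,0.11,0.17,0.22,0.25
2.08,8,0.87,0.13,0.17,0.24,0.31,0.36
2.20,9,0.88,0.15,0.21,0.30,0.37,0.45
2.30,10,0.90,0.18,0.24,0.34,0.43,0.52
2.48,12,0.92,0.21,0.35,0.45,0.58,0.67
2.64,14,0.93,0.24,0.38,0.53,0.66,0.77
2.77,16,0.94,0.29,0.46,0.61,0.76,0.84
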