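# ordagree power table (published reference grid, 10000 replicates)
# hypothesis: beta12_45
# null_or: 3
# margins: 0.2,0.2,0.2,0.2,0.2
beta,or,dd,p_50,p_100,p_150,p_200,p_250
0.00,1,0.00,0.37,0.64,0.80,0.90,0.95
0.69,2,0.50,0.10,0.13,0.17,0.21,0.25
1.10,3,0.67,0.06,0.06,0.05,0.05,0.05
1.39,4,0.75,0.08,0.08,0.10,0.12,0.14
1.61,5,0.80,0.11,0.16,0.21,0.27,0.31
1.79,6,0.83,0.15,0.24,0.33,0.42,0.49
1.95,7,0.86,0.20,0.32,0.44,0.55,0.66
2.08,8,0.87,0.25,0.41,0.55,0.67,0.77
2.20,9,0.88,0.28,0.47,0.63,0.76,0.84
2.30,10,0.90,0.32,0.53,0.71,0.82,0.90
2.48,12,0.92,0.38,0.64,0.81,0.90,0.95
2.64,14,0.93,0.45,0.71,0.87,0.95,0.98
2.77,16,0.94,0.49,0.77,0.91,0.97,0.99
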