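# ordagree power table (published reference grid, 10000 replicates)
# hypothesis: beta12_45
# null_or: 2
# margins: 0.2,0.2,0.2,0.2,0.2
beta,or,dd,p_50,p_100,p_150,p_200,p_250
0.00,1,0.00,0.20,0.37,0.52,0.63,0.74
0.69,2,0.50,0.07,0.05,0.05,0.05,0.04
1.10,3,0.67,0.11,0.12,0.16,0.23,0.26
1.39,4,0.75,0.19,0.32,0.44,0.52,0.61
1.61,5,0.80,0.26,0.46,0.62,0.74,0.82
1.79,6,0.83,0.35,0.58,0.75,0.88,0.94
1.95,7,0.86,0.45,0.68,0.85,0.93,0.97
2.08,8,0.87,0.44,0.74,0.92,0.96,1.00
2.20,9,0.88,0.55,0.84,0.94,0.98,0.99
2.30,10,0.90,0.58,0.87,0.96,0.99,1.00
2.48,12,0.92,0.66,0.91,0.99,0.99,1.00
2.64,14,0.93,0.70,0.94,0.98,1.00,1.00
2.77,16,0.94,0.74,0.95,0.99,1.00,1.00
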