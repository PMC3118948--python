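# ordagree power table (published reference grid, 10000 replicates)
# hypothesis: beta12
# null_or: 2
# margins: 0.2,0.2,0.2,0.2,0.2
beta,or,dd,p_50,p_100,p_150,p_200,p_250
0.00,1,0.00,0.22,0.38,0.51,0.59,0.72
0.69,2,0.50,0.06,0.05,0.05,0.05,0.06
1.10,3,0.67,0.11,0.13,0.17,0.22,0.26
1.39,4,0.75,0.16,0.25,0.41,0.48,0.57
1.61,5,0.80,0.26,0.41,0.56,0.67,0.79
1.79,6,0.83,0.33,0.52,0.70,0.82,0.88
1.95,7,0.86,0.38,0.63,0.78,0.92,0.94
2.08,8,0.87,0.43,0.72,0.85,0.94,0.98
2.20,9,0.88,0.47,0.76,0.90,0.97,0.99
2.30,10,0.90,0.52,0.79,0.94,0.98,0.99
2.48,12,0.92,0.58,0.85,0.96,0.99,1.00
2.64,14,0.93,0.64,0.90,0.97,1.00,1.00
2.77,16,0.94,0.69,0.95,0.99,1.00,1.00
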