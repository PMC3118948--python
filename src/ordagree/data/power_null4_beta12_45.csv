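# ordagree power table (published reference grid, 10000 replicates)
# hypothesis: beta12_45
# null_or: 4
# margins: 0.2,0.2,0.2,0.2,0.2
beta,or,dd,p_50,p_100,p_150,p_200,p_250
0.00,1,0.00,0.45,0.77,0.90,0.97,0.99
0.69,2,0.50,0.14,0.26,0.36,0.44,0.50
1.10,3,0.67,0.08,0.09,0.10,0.13,0.12
1.39,4,0.75,0.05,0.06,0.05,0.05,0.06
1.61,5,0.80,0.06,0.07,0.08,0.07,0.09
1.79,6,0.83,0.08,0.12,0.14,0.16,0.21
1.95,7,0.86,0.12,0.15,0.20,0.24,0.33
2.08,8,0.87,0.13,0.22,0.28,0.38,0.44
2.20,9,0.88,0.20,0.25,0.36,0.47,0.56
2.30,10,0.90,0.20,0.31,0.46,0.55,0.66
2.48,12,0.92,0.26,0.38,0.54,0.67,0.80
2.64,14,0.93,0.28,0.50,0.64,0.77,0.87
2.77,16,0.94,0.35,0.55,0.75,0.87,0.90
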