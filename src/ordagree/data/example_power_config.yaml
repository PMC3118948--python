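# Power grid for a 5-level scale: free beta_{1,2} against a shared log(3)
# for the other adjacent pairs, homogeneous margins.
hypothesis: beta12
null_or: 3
ks: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16]
ns: [50, 100, 150, 200, 250]
margins: homogeneous
alpha: 0.05
nsim: 2000
seed: 1729
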