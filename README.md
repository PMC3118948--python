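# ordagree

Log-linear association models for ordinal agreement tables, category
distinguishability, and Monte-Carlo power analysis for reproducibility
study design.

## The problem

When N objects are rated twice on the same I-category ordinal scale — by
two observers, or by one observer at two times — the ratings form an
I × I agreement table with counts n_ij. Two questions matter for scale
quality: are the raters' marginal distributions homogeneous, and how well
do raters *distinguish* neighbouring categories? The second is captured by
the pairwise odds ratio τ_ij = m_ii m_jj / (m_ij m_ji) and the
Darroch–McCloud degree of distinguishability (DD) δ_ij = 1 − 1/τ_ij
(1 = perfectly distinguishable, 0 = indistinguishable).

`ordagree` fits the family of log-linear association models

```
log m_ij = μ + λ^A_i + λ^B_j − Σ_g β_g x_g(i, j),
x_g(i, j) = (|i − j| / 2) · #{k ∈ g : min(i,j) ≤ k < max(i,j)}
```

where the groups g partition the I − 1 adjacent category pairs:

* **independence** — no association term (agreement by chance only);
* **uniform association (UA)** — one shared β: all adjacent DDs equal,
  τ_ij = e^{β (i−j)²};
* **non-uniform association (NUA)** — per-pair β_{k,k+1}, optionally
  constrained equal within "close" or "symmetric" groups, so DDs may vary
  between adjacent pairs and flag scale defects.

Nested patterns are compared with the deviance difference
ΔG² = G²_null − G²_alt ~ χ²(Δdf). The package also answers the design
question *how many objects must be rated twice* to detect a given
distinguishability defect: it simulates tables from a NUA probability
surface with exactly controlled margins (marginal homogeneity between
raters), estimates the rejection rate of the UA-vs-NUA test over thousands
of replicates, and interpolates required sample sizes from power grids.

## Worked example

A 5-level scale where categories 1 and 2 are indistinguishable
(β_{1,2} = 0, i.e. τ = 1) while the other adjacent pairs have odds ratio 3:

```python
import numpy as np
import ordagree as oa

design = oa.solve_design(250, [0.0, np.log(3), np.log(3), np.log(3)],
                         margins="homogeneous")
table = oa.sample_table(design, np.random.default_rng(7))

ua  = oa.fit_loglinear(table, "uniform")     # H0: all adjacent DDs equal
nua = oa.fit_loglinear(table, "12|2345")     # H1: beta_{1,2} free
print(oa.lr_test(ua, nua))
# LRTestResult(delta_g2=10.387, delta_df=1, p_value=0.00127)

mat = oa.dd_matrix(nua)
print([round(mat.dd[k, k + 1], 3) for k in range(4)])
# [0.001, 0.637, 0.637, 0.637]
```

The test rejects uniform association (p ≈ 0.0013) and the fitted DDs show
the defect: δ_{1,2} ≈ 0 (raters cannot separate categories 1 and 2) while
the other adjacent DDs sit near the generating 2/3.

Sample-size planning uses a power grid (one is packaged for each tested
hypothesis at null odds ratios 2, 3 and 4, estimated at 10000 replicates):

```python
panel = oa.load_reference_table(3, "beta12_23")
print(oa.required_n(panel, beta_query=2.25, target_power=0.80))
# (182.6086956521739, 183)
```

i.e. at least 183 objects are needed for 80% power to detect
β_{1,2} = β_{2,3} = 2.25 against the remaining pairs at log 3. New grids
for other scenarios are produced by `ordagree.power_grid` or the CLI:

```bash
ordagree fit table.csv -p uniform --compare full -o report.txt
ordagree power config.yaml -o grid.csv --seed 1 --nsim 10000
ordagree required-n grid.csv --beta 2.25 --target 0.80
```

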