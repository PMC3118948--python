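# Methods

## Models

Counts n_ij of an I × I agreement table are treated as a full multinomial
M(π, N) with expected means m_ij = N π_ij. All models are log-linear with
free row and column main effects, so fitted margins always reproduce the
observed margins; no marginal-homogeneity constraint is imposed at the
fitting stage (it is a property of the *simulated* truth, not of the
estimator — likelihood-ratio degrees of freedom depend only on the
association grouping).

The association term is built from the adjacent-pair covariate

    x_g(i, j) = (|i − j| / 2) · #{k ∈ g : min(i,j) ≤ k ≤ max(i,j) − 1},

one column −x_g per equality group g of adjacent pairs, giving

    log m_ij = μ + λ^A_i + λ^B_j − Σ_g β_g x_g(i, j).

This coding is pinned by four structural requirements, all verified by the
test suite: (i) merging all groups reduces NUA to UA exactly; (ii) the
adjacent-pair odds ratio is τ_{k,k+1} = e^{β_{k,k+1}}; (iii) under UA,
τ_ij = e^{β (i−j)²}; (iv) the implied DD grows with category distance.
In general log τ_ij = |i − j| · Σ_{k=min}^{max−1} β_{k,k+1}.

Identifiability uses the corner constraint λ^A_1 = λ^B_1 = 0 internally;
reported effects are re-centred to sum to zero. Residual df is
I² − (2I − 1) − (number of groups): 15 for UA on a 5-level scale, and the
UA-vs-NUA comparisons of interest all have Δdf 1 (one-pair-free, close
pairs, symmetric pairs) or 3 (all pairs free, I = 5).

## Estimation and testing

Maximum likelihood is computed on the equivalent Poisson log-linear
likelihood by Newton–Raphson with step-halving whenever a step would
decrease the likelihood. Convergence requires max |score| ≤ 1e-10
(absolute), capped at 100 iterations; a stall at relative machine
precision (score ≤ 1e-9 N, relevant only for totals around 1e5) also
counts as converged. Zero cells are legal data (0 · log 0 = 0 in G²); an
entirely empty observed row or column drives its main effect to −∞ and is
reported as non-convergence rather than raised, so replicated simulation
loops can apply their own failure policy. The deviance is
G² = 2 Σ n_ij log(n_ij / m̂_ij), and nested patterns are compared with
ΔG² ~ χ²(Δdf).

Degrees of distinguishability are reported from the fitted β
(model-based), not from raw counts, because raw tables routinely contain
zeros that make empirical odds ratios undefined; the raw estimator
`empirical_tau` is exposed for diagnostics and errors loudly on zero cells
(no continuity correction).

## Simulating tables with controlled margins

For a target marginal distribution π^S (shared by both raters) and a β
vector, the cell probabilities are

    π_ij = exp(μ + λ_i + λ_j − c(i, j)) / N,
    c(i, j) = (|i − j| / 2) Σ_{k=min}^{max−1} β_k,

with the I + 1 unknowns (μ, λ_1..λ_I) solving the I margin equations
row-sum(π) = π^S plus Σ λ_i = 0 (which keeps μ the overall effect). A
shared λ and the symmetric kernel make π symmetric, so column margins
follow automatically, and π is independent of N (μ absorbs sample size, so
one solved surface serves a whole column of N values).

The system is solved with scipy's dense Powell-hybrid root finder to a
residual of 1e-10; if that fails, a symmetric iterative-proportional /
Sinkhorn scaling of the kernel e^{−c} to the target margins — exact for
this symmetric problem — is used automatically. The solver is sensitive to
initial values on aggressive grids, so grid runs chain warm starts: each
tested odds-ratio value is seeded with the previous solution (the first
with λ = 0, μ = log N + 2·mean(log π^S)). Margins below 1e-3 are allowed
but trigger a warning, since they push λ towards −∞.

## Power estimation

Each replicate draws a table from M(π, N), fits the null (UA) and
alternative (NUA grouping) models, and rejects when the ΔG² p-value is
below α = 0.05 (the conventional level; estimated null rejection rates
confirm calibration). Power/type-I error is the significant fraction among
replicates where both fits converged; failures (possible at small N with
thin margins) are counted and reported separately rather than assigned an
outcome, and a warning fires if they exceed 1% of replicates. Replicate r
of a run seeded s uses the substream seeded (s, r) — results are
reproducible and independent of execution order; grid cells extend the
entropy with their (K, N) indices.

The default study conditions mirror the published 5 × 5 design: null odds
ratio 3 (with 2 and 4 as variants), tested odds ratios
K ∈ {1..10, 12, 14, 16} (β = log K from 0 to 2.77), sample sizes
N ∈ {50, 100, 150, 200, 250}, homogeneous margins (.20 each) plus six
heterogeneous sets, 10000 replicates per cell. The packaged reference
grids cover the three homogeneous-margin hypotheses per null OR; the
published heterogeneous-margin panels are not shipped because their
mapping to specific margin sets is ambiguous in the source — the package
reproduces the qualitative finding (heterogeneous margins lose power)
instead. The test suite runs stochastic checks at 2000 replicates with
correspondingly widened tolerances (~3 Monte-Carlo standard errors); the
acceptance script defaults to the full 10000.

## Interpolation and required sample size

Power grids are stored and interpolated at full precision; two-decimal
rounding (half-up on the decimal value, after stripping binary float
fuzz) is applied only at render time. Power at an intermediate β is linear
between the two bracketing rows, per N column; the required N for a target
power inverts a linear interpolation between the bracketing N columns
using the *unrounded* interpolated powers. This full-precision rule is
what makes hand-checks on printed grids come out right: at β = 2.25 on the
close-pairs null-OR-3 grid the interpolated powers are .725 (N = 150) and
.84 (N = 200), giving N = 182.61 → 183 for 80% power (rounding to the
printed .73 first would give 181.82). No extrapolation: targets outside
the attainable range raise.

## What the simulator does and does not emulate

The generator reproduces the study's idealised conditions: exact NUA
probability surfaces, marginal homogeneity within and between raters, and
multinomial sampling with fixed total N. Real agreement data may violate
all three — rater drift (marginal heterogeneity *between* raters),
overdispersion, structural zeros, or association patterns outside the NUA
family. Passing tests therefore certify the method's behaviour under the
model, not robustness to these departures; rectangular tables, kappa-type
statistics, Bayesian estimation and between-rater heterogeneity are out of
scope.

## Known limitations

* The compact digit-run partition syntax addresses scales up to 9
  categories; larger scales must use the explicit `a-b` pair syntax.
* Power grids assume a single varying group per tested hypothesis; the
  all-pairs-free alternative (Δdf = I − 2, e.g. 3 on a 5-level scale) is
  available through `lr_test` directly but not as a grid label.
* `required_n` searches the first bracketing pair of N columns; on
  non-monotone (noisy) grids near the null this can be ambiguous — use
  finer replication there.
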