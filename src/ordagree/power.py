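"""Monte-Carlo power and type-I error of UA-vs-NUA likelihood-ratio tests.

Each replicate draws a multinomial table from a solved
:class:`~ordagree.simulate.SimulationDesign`, fits the null (UA) and
alternative (NUA) association patterns, and rejects when the G^2 difference
exceeds the chi-squared alpha-quantile with delta-df degrees of freedom.
Power (or, when the generating design satisfies the null, the type-I error)
is the proportion of significant replicates among those where both fits
converged; unconverged replicates (e.g. an empty observed category at small
N) are counted and reported, not silently dropped into either outcome.

Random streams: each replicate uses a substream seeded by
(master seed, replicate counter), so runs are reproducible and replicate
order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import _g_squared, _newton_poisson, build_design
from .partitions import AdjacentPairPartition, as_partition
from .simulate import SimulationDesign, _as_margins, warm_start_path

__all__ = [
    "PowerScenario",
    "PowerEstimate",
    "run_replicate",
    "estimate_power",
    "power_grid",
    "HYPOTHESES",
]

#: Tested-hypothesis labels for the 5-level scale: which adjacent pairs get
#: their own coefficient (the varying group); the remaining pairs share the
#: null coefficient.  "beta12" frees the (1,2) pair, "beta12_23" groups the
#: close pairs {(1,2),(2,3)} against {(3,4),(4,5)}, "beta12_45" groups the
#: symmetric extreme pairs {(1,2),(4,5)} against the intermediate ones.
HYPOTHESES = {
    "beta12": (1,),
    "beta23": (2,),
    "beta34": (3,),
    "beta45": (4,),
    "beta12_23": (1, 2),
    "beta34_45": (3, 4),
    "beta12_45": (1, 4),
    "beta23_34": (2, 3),
}


@dataclass
class PowerScenario:
    """One simulate-fit-test configuration.

    ``design`` is the data-generating truth; the LRT compares
    ``null_partition`` (nested) against ``alt_partition``.
    """

    design: SimulationDesign
    null_partition: AdjacentPairPartition
    alt_partition: AdjacentPairPartition
    alpha: float = 0.05
    nsim: int = 10000
    seed: "int | tuple" = 0

    def __post_init__(self) -> None:
        I = self.design.I
        self.null_partition = as_partition(self.null_partition, I)
        self.alt_partition = as_partition(self.alt_partition, I)
        if not self.null_partition.is_nested_in(self.alt_partition):
            raise ValueError("null partition must be nested in the alternative")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.nsim < 1:
            raise ValueError("nsim must be a positive integer")


@dataclass
class PowerEstimate:
    """Rejection-rate estimate with Monte-Carlo error and failure accounting."""

    p_hat: float
    mc_stderr: float
    n_significant: int
    n_converged: int
    n_failed: int
    scenario: PowerScenario = field(repr=False, default=None)


def _replicate_outcome(pi_flat, N, I, X_null, X_alt, alpha, delta_df, rng, tol, max_iter):
    counts = rng.multinomial(N, pi_flat)
    grid = counts.reshape(I, I)
    if np.any(grid.sum(axis=1) == 0) or np.any(grid.sum(axis=0) == 0):
        return "failed"
    y = counts.astype(float)
    _, m0, _, conv0, _ = _newton_poisson(X_null, y, tol, max_iter)
    if not conv0:
        return "failed"
    _, m1, _, conv1, _ = _newton_poisson(X_alt, y, tol, max_iter)
    if not conv1:
        return "failed"
    delta_g2 = max(_g_squared(y, m0) - _g_squared(y, m1), 0.0)
    p = float(stats.chi2.sf(delta_g2, delta_df))
    return "significant" if p < alpha else "not_significant"


def run_replicate(design, null_partition, alt_partition, alpha, rng,
                  tol: float = 1e-10, max_iter: int = 100) -> str:
    """Draw one table, fit both models, test: 'significant' / 'not_significant' / 'failed'.

    Failures (either fit unconverged) are data for the caller's policy, not
    exceptions.
    """
    I = design.I
    null_partition = as_partition(null_partition, I)
    alt_partition = as_partition(alt_partition, I)
    X_null, _ = build_design(I, null_partition)
    X_alt, _ = build_design(I, alt_partition)
    delta_df = alt_partition.n_groups - null_partition.n_groups
    return _replicate_outcome(
        design.pi.ravel(), design.N, I, X_null, X_alt, alpha, delta_df, rng, tol, max_iter
    )


def _seed_entropy(seed) -> tuple:
    return tuple(seed) if isinstance(seed, (tuple, list)) else (int(seed),)


def estimate_power(scenario: PowerScenario, tol: float = 1e-10, max_iter: int = 100,
                   progress=None) -> PowerEstimate:
    """Aggregate ``nsim`` replicate outcomes into a rejection-rate estimate."""
    design = scenario.design
    I = design.I
    X_null, _ = build_design(I, scenario.null_partition)
    X_alt, _ = build_design(I, scenario.alt_partition)
    delta_df = scenario.alt_partition.n_groups - scenario.null_partition.n_groups
    pi_flat = design.pi.ravel()
    entropy = _seed_entropy(scenario.seed)
    n_sig = n_fail = 0
    for rep in range(scenario.nsim):
        rng = np.random.default_rng((*entropy, rep))
        outcome = _replicate_outcome(
            pi_flat, design.N, I, X_null, X_alt, scenario.alpha, delta_df, rng, tol, max_iter
        )
        if outcome == "failed":
            n_fail += 1
        elif outcome == "significant":
            n_sig += 1
        if progress is not None and (rep + 1) % 500 == 0:
            progress(rep + 1, scenario.nsim)
    n_conv = scenario.nsim - n_fail
    if n_fail > 0.01 * scenario.nsim:
        warnings.warn(
            f"{n_fail}/{scenario.nsim} replicates failed to converge "
            f"(N={design.N}); the rejection rate is conditional on convergence",
            stacklevel=2,
        )
    p_hat = n_sig / n_conv if n_conv else np.nan
    se = float(np.sqrt(p_hat * (1 - p_hat) / n_conv)) if n_conv else np.nan
    return PowerEstimate(p_hat, se, n_sig, n_conv, n_fail, scenario)


def scenario_partitions(hypothesis: str, I: int = 5):
    """Null (UA) and alternative partitions for a tested-hypothesis label."""
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; choose from {sorted(HYPOTHESES)}")
    varying = set(HYPOTHESES[hypothesis])
    fixed = set(range(1, I)) - varying
    if not fixed:
        raise ValueError("hypothesis leaves no pairs at the null value")
    null = AdjacentPairPartition.uniform(I)
    alt = AdjacentPairPartition.from_groups(I, [varying, fixed])
    return null, alt, tuple(sorted(varying))


def power_grid(hypothesis: str, null_or: float, Ks, Ns, margins="homogeneous",
               nsim: int = 10000, seed: int = 0, I: int = 5, alpha: float = 0.05,
               progress=None):
    """Power grid over tested odds ratios K (rows) and sample sizes N (columns).

    Generating tables have the varying pairs of ``hypothesis`` at beta =
    log K and the remaining pairs at log(null_or); the K = null_or row is
    the type-I error.  Designs are solved once per K with warm starts along
    the grid (the probability surface does not depend on N).

    Returns an :class:`ordagree.reporting.PowerTable`.
    """
    from .reporting import PowerTable  # local import to avoid a cycle

    margins = _as_margins(margins)
    if margins.I != I:
        raise ValueError(f"margins are for I={margins.I}, grid is for I={I}")
    null_part, alt_part, varying = scenario_partitions(hypothesis, I)
    Ks = [float(k) for k in Ks]
    Ns = [int(n) for n in Ns]
    beta_configs = []
    for K in Ks:
        betas = np.full(I - 1, np.log(null_or))
        for k in varying:
            betas[k - 1] = np.log(K)
        beta_configs.append(betas)
    base_designs = warm_start_path(max(Ns), beta_configs, margins)

    power = np.empty((len(Ks), len(Ns)))
    stderr = np.empty_like(power)
    n_failed = np.zeros_like(power, dtype=int)
    for ki, base in enumerate(base_designs):
        for ni, N in enumerate(Ns):
            scen = PowerScenario(
                design=base.with_sample_size(N),
                null_partition=null_part,
                alt_partition=alt_part,
                alpha=alpha,
                nsim=nsim,
                seed=(int(seed), ki, ni),
            )
            est = estimate_power(scen)
            power[ki, ni] = est.p_hat
            stderr[ki, ni] = est.mc_stderr
            n_failed[ki, ni] = est.n_failed
            if progress is not None:
                progress(hypothesis, Ks[ki], N, est)
    return PowerTable(
        ns=np.array(Ns),
        betas=np.log(Ks),
        power=power,
        hypothesis=hypothesis,
        null_or=float(null_or),
        margins=tuple(margins.probs),
        ors=np.array(Ks),
        stderr=stderr,
        n_failed=n_failed,
    )
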