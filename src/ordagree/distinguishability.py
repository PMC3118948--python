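"""Odds ratios and Darroch-McCloud degrees of distinguishability.

For categories i and j with cell means m, the pairwise odds ratio is
tau_ij = m_ii m_jj / (m_ij m_ji); tau = 1 means the two categories behave
independently across raters.  The degree of distinguishability (DD) is
delta_ij = 1 - 1/tau_ij: close to 1 the raters separate the categories
almost perfectly, 0 means indistinguishable, negative values flag negative
association.

Under the association models of :mod:`ordagree.model`,
log tau_ij = |i - j| * sum_{k=min(i,j)}^{max(i,j)-1} beta_{k,k+1},
so the whole matrix follows from the I-1 per-pair coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "tau_from_betas",
    "dd_from_tau",
    "empirical_tau",
    "DistinguishabilityMatrix",
    "dd_matrix",
]


def tau_from_betas(i: int, j: int, betas) -> float:
    """Model-based odds ratio tau_ij from per-adjacent-pair coefficients.

    ``betas`` has length I-1; entry k-1 is beta_{k,k+1}.  Equals
    e^{beta_{k,k+1}} for adjacent pairs and e^{beta (i-j)^2} when all
    coefficients are equal.
    """
    betas = np.asarray(betas, dtype=float)
    I = betas.size + 1
    if not (1 <= i <= I and 1 <= j <= I):
        raise IndexError(f"category indices ({i}, {j}) out of range 1..{I}")
    lo, hi = min(i, j), max(i, j)
    return float(np.exp(abs(i - j) * betas[lo - 1 : hi - 1].sum()))


def dd_from_tau(tau: float) -> float:
    """Degree of distinguishability delta = 1 - 1/tau (tau > 0)."""
    if tau <= 0:
        raise ValueError(f"odds ratio must be positive, got {tau}")
    return 1.0 - 1.0 / tau


def empirical_tau(means, i: int, j: int) -> float:
    """Observed odds ratio m_ii m_jj / (m_ij m_ji) from a grid of cell means.

    All four referenced cells must be strictly positive; a zero cell makes
    the odds ratio undefined and raises (no continuity correction applied).
    """
    m = np.asarray(means, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("means must be a square grid")
    I = m.shape[0]
    if not (1 <= i <= I and 1 <= j <= I):
        raise IndexError(f"category indices ({i}, {j}) out of range 1..{I}")
    cells = np.array([m[i - 1, i - 1], m[j - 1, j - 1], m[i - 1, j - 1], m[j - 1, i - 1]])
    if np.any(cells <= 0):
        raise ValueError(
            f"odds ratio for categories ({i}, {j}) undefined: zero cell among "
            "(i,i), (j,j), (i,j), (j,i)"
        )
    return float(cells[0] * cells[1] / (cells[2] * cells[3]))


@dataclass
class DistinguishabilityMatrix:
    """Pairwise odds ratios and degrees of distinguishability.

    ``tau`` and ``dd`` are symmetric I x I grids with unit / zero diagonal
    and dd = 1 - 1/tau elementwise.
    """

    tau: np.ndarray
    dd: np.ndarray

    @property
    def I(self) -> int:  # noqa: E743
        return self.tau.shape[0]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format report: one row (i, j, tau, dd) per unordered pair i < j."""
        rows = [
            (i, j, self.tau[i - 1, j - 1], self.dd[i - 1, j - 1])
            for i in range(1, self.I + 1)
            for j in range(i + 1, self.I + 1)
        ]
        return pd.DataFrame(rows, columns=["i", "j", "tau", "dd"])

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def dd_matrix(fit_or_betas, I: "int | None" = None) -> DistinguishabilityMatrix:
    """All pairwise tau and DD from a converged fit (or a per-pair beta vector).

    Model-based: computed from the fitted association coefficients, not from
    raw counts (raw tables routinely contain zero cells).  An independence
    fit yields tau = 1, dd = 0 everywhere.
    """
    if hasattr(fit_or_betas, "beta_pairs_"):
        fit = fit_or_betas
        if not fit.converged_:
            raise ValueError("cannot compute distinguishabilities from an unconverged fit")
        betas = fit.beta_pairs_
    else:
        betas = np.asarray(fit_or_betas, dtype=float)
        if I is not None and betas.size != I - 1:
            raise ValueError(f"expected {I - 1} per-pair coefficients, got {betas.size}")
    n = betas.size + 1
    tau = np.ones((n, n))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            tau[i - 1, j - 1] = tau[j - 1, i - 1] = tau_from_betas(i, j, betas)
    dd = 1.0 - 1.0 / tau
    return DistinguishabilityMatrix(tau=tau, dd=dd)
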