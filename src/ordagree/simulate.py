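"""Exact cell-probability surfaces and multinomial table sampling.

Given a vector of adjacent-pair association parameters beta and a target
marginal distribution pi^S (the same for both raters: marginal homogeneity
between raters is assumed throughout), the sampling distribution of a table
is the multinomial M(pi, N) whose cell probabilities follow the NUA surface

    pi_ij = exp(mu + lambda_i + lambda_j - c(i, j)) / N,
    c(i, j) = (|i - j| / 2) * sum_{k=min(i,j)}^{max(i,j)-1} beta_k,

with the I + 1 unknowns (mu, lambda_1..lambda_I) solving the nonlinear
system: row sums of pi equal pi^S (I equations) and sum lambda_i = 0 (so mu
stays the overall effect).  A shared lambda plus the symmetric association
kernel makes pi symmetric, hence column margins match automatically.

The system is solved with a dense Newton-type root finder; an iterative
proportional fitting (IPF / Sinkhorn) scaling of the kernel e^{-c} to the
target margins serves as an automatic fallback, valid because both margins
and kernel are symmetric.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import optimize

from .tables import SquareTable

__all__ = [
    "MARGIN_SETS",
    "MarginalSpec",
    "SimulationDesign",
    "cost_matrix",
    "solve_design",
    "warm_start_path",
    "sample_table",
]

#: Marginal-probability sets used in the 5 x 5 simulation study.
MARGIN_SETS = {
    "homogeneous": (0.20, 0.20, 0.20, 0.20, 0.20),
    "few_first": (0.05, 0.24, 0.24, 0.24, 0.23),
    "few_intermediate": (0.24, 0.05, 0.24, 0.24, 0.23),
    "few_central": (0.24, 0.24, 0.05, 0.24, 0.23),
    "few_extremes": (0.05, 0.30, 0.30, 0.30, 0.05),
    "few_first_two": (0.05, 0.05, 0.30, 0.30, 0.30),
    "heterogeneous": (0.05, 0.15, 0.40, 0.30, 0.10),
}


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal category probabilities pi^S (shared by both raters)."""

    probs: tuple

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        arr = np.asarray(probs)
        if arr.size < 2:
            raise ValueError("need at least 2 categories")
        if np.any(arr <= 0):
            raise ValueError("all marginal probabilities must be strictly positive")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"marginal probabilities must sum to 1, got {arr.sum()!r}")
        if np.any(arr < 1e-3):
            warnings.warn(
                "marginal probabilities below 1e-3 push main effects toward -inf "
                "and can slow the design solver",
                stacklevel=2,
            )

    @property
    def I(self) -> int:  # noqa: E743
        return len(self.probs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs)


def _as_margins(margins) -> MarginalSpec:
    if isinstance(margins, MarginalSpec):
        return margins
    if isinstance(margins, str):
        try:
            return MarginalSpec(MARGIN_SETS[margins])
        except KeyError:
            raise ValueError(
                f"unknown margin set {margins!r}; available: {sorted(MARGIN_SETS)}"
            ) from None
    return MarginalSpec(tuple(margins))


def cost_matrix(betas) -> np.ndarray:
    """Symmetric association kernel exponent c(i, j) from per-pair betas."""
    betas = np.asarray(betas, dtype=float)
    I = betas.size + 1
    c = np.zeros((I, I))
    for i in range(1, I + 1):
        for j in range(i + 1, I + 1):
            c[i - 1, j - 1] = c[j - 1, i - 1] = 0.5 * (j - i) * betas[i - 1 : j - 1].sum()
    return c


@dataclass(frozen=True)
class SimulationDesign:
    """A solved sampling distribution for I x I agreement tables.

    ``pi`` is the symmetric cell-probability grid; ``mu`` and ``lambdas``
    are the solved log-linear parameters (sum of lambdas = 0, mu absorbs the
    sample size N through m_ij = N pi_ij).
    """

    N: int
    betas: tuple
    margins: MarginalSpec
    mu: float
    lambdas: np.ndarray
    pi: np.ndarray

    @property
    def I(self) -> int:  # noqa: E743
        return self.margins.I

    @property
    def expected_counts(self) -> np.ndarray:
        return self.N * self.pi

    def residuals(self) -> np.ndarray:
        """Residuals of the defining system (I margin equations + sum-lambda)."""
        c = cost_matrix(self.betas)
        lam = self.lambdas
        pi = np.exp(self.mu + lam[:, None] + lam[None, :] - c) / self.N
        return np.append(pi.sum(axis=1) - self.margins.as_array(), lam.sum())

    def with_sample_size(self, N: int) -> "SimulationDesign":
        """Same probability surface at a different N (mu absorbs the change)."""
        if N < 1:
            raise ValueError("N must be a positive integer")
        return replace(self, N=int(N), mu=self.mu + np.log(N / self.N))

    # ------------------------------------------------------------------ #
    # CSV round-trip
    # ------------------------------------------------------------------ #
    def to_csv(self, path) -> None:
        buf = io.StringIO()
        buf.write("# ordagree simulation design\n")
        buf.write(f"# N: {self.N}\n")
        buf.write(f"# mu: {self.mu!r}\n")
        buf.write(f"# lambdas: {','.join(repr(float(v)) for v in self.lambdas)}\n")
        buf.write(f"# betas: {','.join(repr(float(b)) for b in self.betas)}\n")
        buf.write(f"# margins: {','.join(repr(p) for p in self.margins.probs)}\n")
        for row in self.pi:
            buf.write(",".join(repr(float(v)) for v in row) + "\n")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "SimulationDesign":
        meta: dict[str, str] = {}
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = value.strip()
            elif line.strip():
                rows.append([float(v) for v in line.split(",")])
        return cls(
            N=int(meta["N"]),
            betas=tuple(float(v) for v in meta["betas"].split(",")),
            margins=MarginalSpec(tuple(float(v) for v in meta["margins"].split(","))),
            mu=float(meta["mu"]),
            lambdas=np.array([float(v) for v in meta["lambdas"].split(",")]),
            pi=np.array(rows),
        )


def _system(v: np.ndarray, c: np.ndarray, probs: np.ndarray, N: int) -> np.ndarray:
    mu, lam = v[0], v[1:]
    eta = mu + lam[:, None] + lam[None, :] - c
    pi = np.exp(np.minimum(eta, 60.0)) / N
    return np.append(pi.sum(axis=1) - probs, lam.sum())


def _ipf_solution(c: np.ndarray, probs: np.ndarray, tol: float = 1e-13, max_iter: int = 50000):
    """Symmetric diagonal scaling of the kernel e^{-c} to the target margins."""
    K = np.exp(-c)
    r = probs.copy()
    for _ in range(max_iter):
        Kr = K @ r
        err = np.max(np.abs(r * Kr - probs))
        if err <= tol:
            break
        r = np.sqrt(r * probs / Kr)
    return r


def solve_design(N: int, betas, margins, init=None, tol: float = 1e-10) -> SimulationDesign:
    """Solve the marginal-constraint system and return the sampling design.

    Parameters
    ----------
    N : int
        Sample size (number of objects rated twice).
    betas : length I-1 sequence
        Adjacent-pair association parameters beta_{k,k+1}.
    margins : MarginalSpec, sequence of probabilities, or named set
        Target marginal distribution (one of ``MARGIN_SETS`` by name).
    init : (mu, lambdas), optional
        Warm start; defaults to lambda = 0 and
        mu = log N + 2 mean(log margins).
    tol : float
        Max absolute residual accepted for the solved system.
    """
    margins = _as_margins(margins)
    betas = tuple(float(b) for b in betas)
    I = margins.I
    if len(betas) != I - 1:
        raise ValueError(f"expected {I - 1} association parameters, got {len(betas)}")
    if N < 1:
        raise ValueError("N must be a positive integer")
    probs = margins.as_array()
    c = cost_matrix(betas)

    if init is None:
        x0 = np.concatenate([[np.log(N) + 2 * np.mean(np.log(probs))], np.zeros(I)])
    else:
        mu0, lam0 = init
        x0 = np.concatenate([[float(mu0)], np.asarray(lam0, dtype=float)])

    sol = optimize.root(_system, x0, args=(c, probs, N), method="hybr", options={"xtol": 1e-13})
    v = sol.x
    if np.max(np.abs(_system(v, c, probs, N))) > tol:
        # IPF fallback: exact for this symmetric problem, slower but robust.
        r = _ipf_solution(c, probs)
        logr = np.log(r)
        v = np.concatenate([[np.log(N) + 2 * logr.mean()], logr - logr.mean()])
        resid = np.max(np.abs(_system(v, c, probs, N)))
        if resid > tol:
            raise RuntimeError(
                f"design solver failed: residual norm {resid:.3e} > {tol:.1e}; "
                "consider a warm start from a nearby solved design"
            )
    mu, lam = float(v[0]), v[1:]
    pi = np.exp(mu + lam[:, None] + lam[None, :] - c) / N
    return SimulationDesign(N=int(N), betas=betas, margins=margins, mu=mu, lambdas=lam, pi=pi)


def warm_start_path(N: int, beta_configs, margins, tol: float = 1e-10) -> list:
    """Solve a sequence of designs, seeding each solve with the previous solution.

    The marginal system is sensitive to initial values; walking an ordered
    grid of tested odds ratios and chaining solutions avoids spurious roots.
    """
    designs: list[SimulationDesign] = []
    init = None
    for idx, betas in enumerate(beta_configs):
        try:
            d = solve_design(N, betas, margins, init=init, tol=tol)
        except RuntimeError as exc:
            raise RuntimeError(f"design {idx} (betas={tuple(betas)}) failed: {exc}") from exc
        designs.append(d)
        init = (d.mu, d.lambdas)
    return designs


def sample_table(design: SimulationDesign, rng: np.random.Generator) -> SquareTable:
    """Draw one I x I table from the multinomial M(pi, N)."""
    counts = rng.multinomial(design.N, design.pi.ravel()).reshape(design.I, design.I)
    return SquareTable(counts)
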