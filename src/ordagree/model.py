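"""Log-linear association models for square ordinal agreement tables.

The independence model for cell means m_ij of an I x I agreement table is

    log m_ij = mu + lambda^A_i + lambda^B_j,

agreement being due to chance only.  Ordinal scales induce association that
strengthens with category distance; the uniform-association (UA) model adds
one association parameter beta shared by all adjacent category pairs, and
non-uniform association (NUA) models free one parameter beta_{k,k+1} per
adjacent pair (k, k+1), optionally constrained equal within groups:

    log m_ij = mu + lambda^A_i + lambda^B_j - sum_g beta_g x_g(i, j),

with covariate x_g(i, j) = (|i-j| / 2) * #{k in g : min(i,j) <= k < max(i,j)}.
Under this coding the pairwise odds ratio tau_ij = m_ii m_jj / (m_ij m_ji)
satisfies log tau_ij = |i-j| * sum of the per-pair betas between i and j, so
adjacent pairs have tau_{k,k+1} = e^{beta_{k,k+1}} and the UA special case
gives tau_ij = e^{beta (i-j)^2}.

Estimation maximises the Poisson log-likelihood (equivalent to the
multinomial kernel for these hierarchical models) by Newton-Raphson with
step-halving.  Nested models are compared with the G^2 deviance difference,
chi-squared with delta-df degrees of freedom.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .partitions import AdjacentPairPartition, as_partition
from .tables import SquareTable, validate_counts

__all__ = [
    "association_covariate",
    "build_design",
    "LogLinearAssociation",
    "fit_loglinear",
    "LRTestResult",
    "lr_test",
]


def association_covariate(i: int, j: int, group, I: "int | None" = None) -> float:
    """Association covariate x_g(i, j) for one equality group of adjacent pairs.

    x_g(i, j) = (|i - j| / 2) * #{k in group : min(i,j) <= k <= max(i,j) - 1}.
    Symmetric in (i, j) and zero on the diagonal.
    """
    if I is not None and not (1 <= i <= I and 1 <= j <= I):
        raise IndexError(f"category indices ({i}, {j}) out of range 1..{I}")
    lo, hi = (i, j) if i <= j else (j, i)
    crossed = sum(1 for k in group if lo <= k <= hi - 1)
    return 0.5 * abs(i - j) * crossed


def build_design(I: int, partition: "str | AdjacentPairPartition"):
    """Cells x parameters design matrix for the log-linear predictor.

    Columns: intercept; I-1 row-effect indicators (corner constraint
    lambda^A_1 = 0); I-1 column-effect indicators (lambda^B_1 = 0); one
    column of -x_g per association group.  Rows are cells (i, j) in
    row-major order.

    Returns
    -------
    X : (I*I, 2I-1+n_groups) float array
    names : list of str
        Parameter names matching the columns.
    """
    part = as_partition(partition, I)
    p = 2 * I - 1 + part.n_groups
    X = np.zeros((I * I, p))
    names = ["mu"]
    names += [f"rowA[{i}]" for i in range(2, I + 1)]
    names += [f"colB[{j}]" for j in range(2, I + 1)]
    names += [f"beta[{'_'.join(str(k) for k in sorted(g))}]" for g in part.groups]
    idx = 0
    for i in range(1, I + 1):
        for j in range(1, I + 1):
            X[idx, 0] = 1.0
            if i > 1:
                X[idx, i - 1] = 1.0
            if j > 1:
                X[idx, I - 1 + j - 1] = 1.0
            for g_idx, g in enumerate(part.groups):
                X[idx, 2 * I - 2 + 1 + g_idx] = -association_covariate(i, j, g)
            idx += 1
    return X, names


def _newton_poisson(X: np.ndarray, y: np.ndarray, tol: float, max_iter: int):
    """Newton-Raphson ML for a Poisson log-linear model.

    Convergence criterion: max absolute score <= tol.  Step-halving guards
    against likelihood decreases; overflow in exp simply produces -inf
    likelihood and triggers a halved step.
    """
    p = X.shape[1]
    theta = np.zeros(p)
    theta[0] = np.log(max(y.mean(), 0.5))

    def loglik(eta):
        with np.errstate(over="ignore"):
            m = np.exp(eta)
        return float(y @ eta - m.sum())

    eta = X @ theta
    ll = loglik(eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m = np.exp(np.minimum(eta, 700.0))
        score = X.T @ (y - m)
        if np.max(np.abs(score)) <= tol:
            converged = True
            break
        H = (X * m[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(40):
            theta_new = theta + t * step
            eta_new = X @ theta_new
            ll_new = loglik(eta_new)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            break
        theta, eta, ll = theta_new, eta_new, ll_new
    m = np.exp(eta)
    if not converged:
        # Very large totals put the attainable score floor above an absolute
        # 1e-10; a stall at relative machine precision still counts.
        score = X.T @ (y - m)
        if np.max(np.abs(score)) <= 1e-9 * max(1.0, y.sum()):
            converged = True
    return theta, m, ll, converged, it


def _g_squared(y: np.ndarray, m: np.ndarray) -> float:
    """Deviance G^2 = 2 sum n log(n / m) with the 0 log 0 = 0 convention."""
    pos = y > 0
    return float(2.0 * np.sum(y[pos] * np.log(y[pos] / m[pos])))


class LogLinearAssociation(BaseEstimator):
    """Maximum-likelihood fit of an independence / UA / NUA log-linear model.

    Parameters
    ----------
    partition : str or AdjacentPairPartition, default "uniform"
        Equality grouping of the adjacent-pair association parameters:
        "uniform", "independence", "full", or a compact group string such as
        ``"12|2345"`` (see :func:`ordagree.partitions.parse_partition`).
    tol : float, default 1e-10
        Convergence tolerance on the maximum absolute score.
    max_iter : int, default 100
        Newton iteration cap.

    Attributes
    ----------
    I_ : int
        Scale size.
    partition_ : AdjacentPairPartition
        Resolved partition.
    mu_, row_effects_, col_effects_ : overall and main effects, re-centred
        to sum-to-zero for reporting (fitting uses the corner constraint
        lambda_1 = 0).
    betas_ : (n_groups,) array
        One association coefficient per equality group, in group order.
    beta_pairs_ : (I-1,) array
        Per-adjacent-pair expansion of ``betas_`` (zeros under independence).
    fitted_means_ : (I, I) array
        Fitted cell means; rows/columns reproduce the observed margins.
    log_likelihood_ : float
        Poisson kernel log-likelihood sum(n log m - m).
    g_squared_ : float
        Deviance against the saturated model.
    df_resid_ : int
        I^2 - (2I - 1) - n_groups.
    converged_ : bool
    n_iter_ : int
    message_ : str
    """

    def __init__(self, partition="uniform", tol: float = 1e-10, max_iter: int = 100):
        self.partition = partition
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "LogLinearAssociation":
        """Fit the model to an I x I table of counts (array or SquareTable)."""
        if isinstance(X, SquareTable):
            X = X.counts
        counts = validate_counts(X)
        I = counts.shape[0]
        part = as_partition(self.partition, I)
        self.I_ = I
        self.partition_ = part
        self.counts_ = counts
        self.df_resid_ = I * I - (2 * I - 1) - part.n_groups
        design, names = build_design(I, part)
        self.param_names_ = names
        yv = counts.ravel().astype(float)

        if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
            # An empty observed row/column drives its main effect to -inf:
            # report as rank deficiency / non-convergence, never raise, so
            # replicated simulation loops can apply their failure policy.
            self.converged_ = False
            self.n_iter_ = 0
            self.message_ = "empty observed row or column: main effect unbounded"
            self.mu_ = np.nan
            self.row_effects_ = np.full(I, np.nan)
            self.col_effects_ = np.full(I, np.nan)
            self.betas_ = np.full(part.n_groups, np.nan)
            self.beta_pairs_ = np.full(I - 1, np.nan)
            self.fitted_means_ = np.full((I, I), np.nan)
            self.log_likelihood_ = np.nan
            self.g_squared_ = np.nan
            return self

        theta, m, ll, converged, it = _newton_poisson(design, yv, self.tol, self.max_iter)

        row_raw = np.concatenate([[0.0], theta[1:I]])
        col_raw = np.concatenate([[0.0], theta[I : 2 * I - 1]])
        self.mu_ = float(theta[0] + row_raw.mean() + col_raw.mean())
        self.row_effects_ = row_raw - row_raw.mean()
        self.col_effects_ = col_raw - col_raw.mean()
        self.betas_ = theta[2 * I - 1 :].copy()
        self.beta_pairs_ = part.expand(self.betas_)
        self.fitted_means_ = m.reshape(I, I)
        self.log_likelihood_ = ll
        self.g_squared_ = _g_squared(yv, m)
        self.converged_ = bool(converged)
        self.n_iter_ = it
        self.message_ = "converged" if converged else "iteration cap or singular Hessian"
        return self

    def score(self, X, y=None) -> float:
        """Poisson kernel log-likelihood of a table under the fitted means."""
        if isinstance(X, SquareTable):
            X = X.counts
        counts = validate_counts(X)
        m = self.fitted_means_
        return float(np.sum(counts * np.log(m)) - m.sum())


def fit_loglinear(table, partition="uniform", **kwargs) -> LogLinearAssociation:
    """Fit a log-linear association model; thin wrapper over the estimator."""
    return LogLinearAssociation(partition=partition, **kwargs).fit(table)


class LRTestResult(NamedTuple):
    delta_g2: float
    delta_df: int
    p_value: float


def lr_test(fit_null: LogLinearAssociation, fit_alt: LogLinearAssociation) -> LRTestResult:
    """Likelihood-ratio test of a null association pattern against a nested-richer one.

    delta G^2 = G^2_null - G^2_alt is referred to the chi-squared
    distribution with delta df = n_groups(alt) - n_groups(null).
    """
    for f, which in ((fit_null, "null"), (fit_alt, "alternative")):
        if not getattr(f, "converged_", False):
            raise ValueError(f"{which} fit did not converge")
    if not fit_null.partition_.is_nested_in(fit_alt.partition_):
        raise ValueError("null partition is not nested in the alternative partition")
    if not np.array_equal(fit_null.counts_, fit_alt.counts_):
        raise ValueError("fits are for different tables")
    delta_df = fit_alt.partition_.n_groups - fit_null.partition_.n_groups
    delta_g2 = fit_null.g_squared_ - fit_alt.g_squared_
    if delta_g2 < -1e-6:
        raise ValueError(f"negative deviance difference {delta_g2}: fits inconsistent")
    delta_g2 = max(delta_g2, 0.0)
    p = float(stats.chi2.sf(delta_g2, delta_df)) if delta_df > 0 else 1.0
    return LRTestResult(delta_g2, delta_df, p)
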