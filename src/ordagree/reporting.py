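"""Power tables: CSV round-trip, interpolation, and required sample size.

A power table holds rejection-rate estimates on a (beta, N) grid, one row
per tested association parameter beta = log K and one column per sample
size.  All storage and arithmetic is full precision; two-decimal rounding
is applied only when rendering — which is exactly what makes inverse
interpolation of required sample sizes reproducible from published grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PowerTable",
    "read_power_table",
    "write_power_table",
    "interp_power_at_beta",
    "required_n",
    "round2",
    "reference_table_names",
    "load_reference_table",
]


def round2(x: float) -> float:
    """Two-decimal display rounding, half away from zero on the decimal value.

    Float fuzz is removed first (0.72499999999999998 is the binary image of
    0.725 and must round to 0.73, matching hand arithmetic on printed
    grids).
    """
    d = Decimal(str(round(float(x), 10)))
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PowerTable:
    """Grid of power estimates: rows = tested beta = log K, columns = N."""

    ns: np.ndarray
    betas: np.ndarray
    power: np.ndarray
    hypothesis: str = ""
    null_or: float = math.nan
    margins: "tuple | None" = None
    ors: "np.ndarray | None" = None
    dd: "np.ndarray | None" = None
    stderr: "np.ndarray | None" = field(default=None, repr=False)
    n_failed: "np.ndarray | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ns = np.asarray(self.ns, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.betas.size, self.ns.size):
            raise ValueError(
                f"power grid shape {self.power.shape} does not match "
                f"({self.betas.size} betas, {self.ns.size} sample sizes)"
            )
        if np.any(np.diff(self.ns) <= 0):
            raise ValueError("sample-size columns must be strictly increasing")
        if np.any(np.diff(self.betas) <= 0):
            raise ValueError("beta rows must be strictly increasing")
        if self.ors is None:
            self.ors = np.exp(self.betas)
        else:
            self.ors = np.asarray(self.ors, dtype=float)
        if self.dd is None:
            self.dd = 1.0 - 1.0 / self.ors
        else:
            self.dd = np.asarray(self.dd, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        cols = {"beta": self.betas, "or": self.ors, "dd": self.dd}
        for k, n in enumerate(self.ns):
            cols[f"p_{int(n)}"] = self.power[:, k]
        for k, n in enumerate(self.ns):
            cols[f"ge80_{int(n)}"] = np.array([round2(v) >= 0.80 for v in self.power[:, k]])
        if self.stderr is not None:
            for k, n in enumerate(self.ns):
                cols[f"se_{int(n)}"] = self.stderr[:, k]
        if self.n_failed is not None:
            for k, n in enumerate(self.ns):
                cols[f"fail_{int(n)}"] = self.n_failed[:, k]
        return pd.DataFrame(cols)

    def render(self) -> str:
        """Two-decimal presentation of the grid (power columns only)."""
        df = self.to_frame()
        keep = ["beta", "or", "dd"] + [c for c in df.columns if c.startswith("p_")]
        df = df[keep].copy()
        for c in keep:
            if c != "or":
                df[c] = df[c].map(lambda v: f"{round2(v):.2f}")
        return df.to_string(index=False)


def write_power_table(table: PowerTable, path, extra_header: "dict | None" = None) -> None:
    """Write a power table as CSV with metadata comment lines, full precision."""
    lines = ["# ordagree power table"]
    meta = {
        "hypothesis": table.hypothesis,
        "null_or": repr(table.null_or),
        "margins": ",".join(repr(p) for p in table.margins) if table.margins else "",
    }
    if extra_header:
        meta.update({k: str(v) for k, v in extra_header.items()})
    lines += [f"# {k}: {v}" for k, v in meta.items() if v]
    # default str() formatting is the shortest round-trip representation
    csv = table.to_frame().to_csv(index=False)
    Path(path).write_text("\n".join(lines) + "\n" + csv)


def read_power_table(path) -> PowerTable:
    """Read a power-table CSV (metadata comments optional; DD recomputed if absent)."""
    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition(":")
        if value:
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "beta" not in df.columns:
        raise ValueError(f"{path}: malformed header, no 'beta' column")
    p_cols = [c for c in df.columns if c.startswith("p_")]
    if not p_cols:
        raise ValueError(f"{path}: no power columns 'p_<N>'")
    try:
        ns = [int(c[2:]) for c in p_cols]
    except ValueError:
        raise ValueError(f"{path}: malformed power column names {p_cols}") from None
    order = np.argsort(ns)
    ns_sorted = np.array(ns)[order]
    if np.any(np.diff(ns_sorted) <= 0):
        raise ValueError(f"{path}: sample-size columns not strictly increasing")
    power = df[[p_cols[k] for k in order]].to_numpy()
    se_cols = [f"se_{n}" for n in ns_sorted]
    fail_cols = [f"fail_{n}" for n in ns_sorted]
    margins = None
    if meta.get("margins"):
        margins = tuple(float(v) for v in meta["margins"].split(","))
    return PowerTable(
        ns=ns_sorted,
        betas=df["beta"].to_numpy(),
        power=power,
        hypothesis=meta.get("hypothesis", ""),
        null_or=float(meta["null_or"]) if "null_or" in meta else math.nan,
        margins=margins,
        ors=df["or"].to_numpy() if "or" in df.columns else None,
        dd=df["dd"].to_numpy() if "dd" in df.columns else None,
        stderr=df[se_cols].to_numpy() if all(c in df.columns for c in se_cols) else None,
        n_failed=df[fail_cols].to_numpy() if all(c in df.columns for c in fail_cols) else None,
    )


def interp_power_at_beta(table: PowerTable, beta_query: float) -> np.ndarray:
    """Per-N power at an intermediate beta, linear between the bracketing rows.

    Interpolation runs on full-precision stored values; round for display
    with :func:`round2`.
    """
    b = table.betas
    if not (b[0] <= beta_query <= b[-1]):
        raise ValueError(f"beta {beta_query} outside the table range [{b[0]}, {b[-1]}]")
    hi = int(np.searchsorted(b, beta_query))
    if hi < b.size and b[hi] == beta_query:
        return table.power[hi].copy()
    lo = hi - 1
    w = (beta_query - b[lo]) / (b[hi] - b[lo])
    return (1 - w) * table.power[lo] + w * table.power[hi]


def required_n(table: PowerTable, beta_query: float, target_power: float):
    """Smallest sample size reaching a target power at a given beta.

    Interpolates the power column-wise at ``beta_query`` (full precision),
    then inverse-linearly in N between the bracketing columns.  Returns
    ``(n_real, n_integer)`` with ``n_integer = ceil(n_real)``.  Raises if
    the target is outside the attainable range on the grid (no
    extrapolation).
    """
    p = interp_power_at_beta(table, beta_query)
    ns = table.ns
    exact = np.where(np.abs(p - target_power) < 1e-12)[0]
    if exact.size:
        n = float(ns[exact[0]])
        return n, int(math.ceil(n - 1e-9))
    if not (min(p[0], p[-1]) < target_power < max(p[0], p[-1])):
        raise ValueError(
            f"target power {target_power} not attainable on the N grid "
            f"(interpolated powers span [{p.min():.4g}, {p.max():.4g}])"
        )
    for k in range(p.size - 1):
        lo, hi = p[k], p[k + 1]
        if lo != hi and min(lo, hi) < target_power < max(lo, hi):
            n_real = ns[k] + (ns[k + 1] - ns[k]) * (target_power - lo) / (hi - lo)
            return float(n_real), int(math.ceil(n_real - 1e-9))
    raise ValueError(f"target power {target_power} not bracketed by adjacent N columns")


# --------------------------------------------------------------------- #
# published 5x5 reference grids (homogeneous-margin panels)
# --------------------------------------------------------------------- #
_REFERENCE_FILES = {
    (3.0, "beta12"): "power_null3_beta12.csv",
    (3.0, "beta12_23"): "power_null3_beta12_23.csv",
    (3.0, "beta12_45"): "power_null3_beta12_45.csv",
    (2.0, "beta12"): "power_null2_beta12.csv",
    (2.0, "beta12_23"): "power_null2_beta12_23.csv",
    (2.0, "beta12_45"): "power_null2_beta12_45.csv",
    (4.0, "beta12"): "power_null4_beta12.csv",
    (4.0, "beta12_23"): "power_null4_beta12_23.csv",
    (4.0, "beta12_45"): "power_null4_beta12_45.csv",
}


def reference_table_names():
    """(null odds ratio, hypothesis label) keys of the shipped published grids."""
    return sorted(_REFERENCE_FILES)


def load_reference_table(null_or: float, hypothesis: str) -> PowerTable:
    """Load a published 5x5 homogeneous-margin power grid (10000-replicate study)."""
    key = (float(null_or), hypothesis)
    if key not in _REFERENCE_FILES:
        raise ValueError(f"no reference table for {key}; available: {reference_table_names()}")
    with resources.as_file(
        resources.files("ordagree.data") / _REFERENCE_FILES[key]
    ) as p:
        return read_power_table(p)
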