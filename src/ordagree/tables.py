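"""Square agreement tables and their CSV round-trip.

An agreement table cross-classifies N objects rated by two raters (or one
rater twice) on the same I-category ordinal scale: cell (i, j) counts the
objects rated i by rater A (rows) and j by rater B (columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SquareTable", "read_table_csv", "write_table_csv"]


def validate_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"counts must be a square matrix, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("need at least a 2 x 2 table")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    arr = arr.astype(np.int64)
    if arr.sum() < 1:
        raise ValueError("table must contain at least one observation")
    return arr


@dataclass
class SquareTable:
    """Observed counts of an I x I cross-classification.

    Attributes
    ----------
    counts : (I, I) int array
        Non-negative cell counts n_ij, rows = rater A, columns = rater B.
    labels : list of str, optional
        Category labels, used only for CSV headers.
    """

    counts: np.ndarray
    labels: "list[str] | None" = field(default=None)

    def __post_init__(self) -> None:
        self.counts = validate_counts(self.counts)
        if self.labels is not None and len(self.labels) != self.I:
            raise ValueError("labels length must equal the number of categories")

    @property
    def I(self) -> int:  # noqa: E743 - field name from the domain
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_csv(cls, path) -> "SquareTable":
        return read_table_csv(path)

    def to_csv(self, path) -> None:
        write_table_csv(self, path)


def read_table_csv(path) -> SquareTable:
    """Read an I x I integer table, with an optional single header row of labels."""
    path = Path(path)
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = not np.issubdtype(np.asarray(first).dtype, np.number)
    if has_header:
        df = pd.read_csv(path)
        labels = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, header=None)
        labels = None
    return SquareTable(df.to_numpy(), labels=labels)


def write_table_csv(table: SquareTable, path) -> None:
    df = pd.DataFrame(table.counts, columns=table.labels)
    df.to_csv(path, index=False, header=table.labels is not None)
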