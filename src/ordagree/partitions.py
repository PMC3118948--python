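"""Groupings of adjacent-category association parameters.

A square I x I agreement table has I - 1 *adjacent pairs* of categories:
pair k is the category pair (k, k+1), k = 1, ..., I-1.  Association models
attach one log-odds-ratio parameter beta_{k,k+1} to each pair; equality
constraints between those parameters are expressed as a partition of the
pair indices into groups sharing one coefficient.

Special cases:

* one group containing every pair     -> uniform association (UA),
* I - 1 singleton groups              -> full non-uniform association (NUA),
* zero groups                         -> independence (no association term).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["AdjacentPairPartition", "as_partition", "parse_partition"]


@dataclass(frozen=True)
class AdjacentPairPartition:
    """Partition of the adjacent-pair indices {1, ..., I-1} into equality groups.

    Parameters
    ----------
    I : int
        Number of categories of the rating scale (I >= 2; I >= 3 for a
        partition with more than one group).
    groups : tuple of frozenset of int
        Ordered, pairwise-disjoint, non-empty sets of pair indices whose
        union is exactly {1, ..., I-1}.  The empty tuple is the
        *independence* variant (no association term at all).
    """

    I: int
    groups: tuple[frozenset[int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.I < 2:
            raise ValueError(f"need at least 2 categories, got I={self.I}")
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        full = set(range(1, self.I))
        if not groups:  # independence
            return
        seen: set[int] = set()
        for g in groups:
            if not g:
                raise ValueError("empty group in partition")
            if not g <= full:
                raise ValueError(f"pair indices {sorted(g - full)} out of range 1..{self.I - 1}")
            if g & seen:
                raise ValueError(f"pair indices {sorted(g & seen)} appear in more than one group")
            seen |= g
        if seen != full:
            raise ValueError(
                f"groups must cover all pair indices 1..{self.I - 1}; missing {sorted(full - seen)}"
            )

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def uniform(cls, I: int) -> "AdjacentPairPartition":
        """All adjacent pairs share one association parameter (UA model)."""
        return cls(I, (frozenset(range(1, I)),))

    @classmethod
    def independence(cls, I: int) -> "AdjacentPairPartition":
        """No association term: ratings statistically independent."""
        return cls(I, ())

    @classmethod
    def full(cls, I: int) -> "AdjacentPairPartition":
        """One free parameter per adjacent pair (full NUA model)."""
        return cls(I, tuple(frozenset({k}) for k in range(1, I)))

    @classmethod
    def from_groups(cls, I: int, groups: Iterable[Iterable[int]]) -> "AdjacentPairPartition":
        return cls(I, tuple(frozenset(g) for g in groups))

    # ------------------------------------------------------------------ #
    # properties
    # ------------------------------------------------------------------ #
    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def is_independence(self) -> bool:
        return not self.groups

    @property
    def is_uniform(self) -> bool:
        return len(self.groups) == 1

    def label(self) -> str:
        if self.is_independence:
            return "independence"
        if self.is_uniform:
            return "uniform"
        parts = []
        for g in self.groups:
            parts.append(",".join(f"{k}-{k + 1}" for k in sorted(g)))
        return "|".join(parts)

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #
    def is_nested_in(self, other: "AdjacentPairPartition") -> bool:
        """True if a model with this partition is a special case of ``other``.

        Independence is nested in everything; otherwise the *other* (richer)
        partition must refine this one, i.e. every group of ``other`` sits
        inside one group of ``self``.
        """
        if self.I != other.I:
            return False
        if self.is_independence:
            return True
        if other.is_independence:
            return self.is_independence
        return all(any(g <= h for h in self.groups) for g in other.groups)

    def expand(self, group_values: Sequence[float]) -> np.ndarray:
        """Map one value per group to a length I-1 per-pair coefficient vector.

        The independence variant expands to all zeros.
        """
        out = np.zeros(self.I - 1)
        if self.is_independence:
            return out
        if len(group_values) != self.n_groups:
            raise ValueError(f"expected {self.n_groups} group values, got {len(group_values)}")
        for value, g in zip(group_values, self.groups):
            for k in g:
                out[k - 1] = value
        return out


def parse_partition(spec: str, I: int) -> AdjacentPairPartition:
    """Parse a compact partition string.

    Accepted forms (pair k is the category pair (k, k+1)):

    * ``"uniform"`` / ``"ua"``: one shared parameter;
    * ``"independence"`` / ``"indep"``: no association term;
    * ``"full"`` / ``"nua"``: all parameters free;
    * groups separated by ``|``, each group a comma-separated list of category
      pairs written either as a run of consecutive category digits
      (``"2345"`` = pairs 2-3, 3-4, 4-5) or as an explicit pair ``"a-b"``
      with b = a + 1.  Example: ``"12|2345"`` frees beta_{1,2} against the
      rest; ``"1-2,4-5|2-3,3-4"`` is the symmetric-extremes grouping.
    """
    s = spec.strip().lower()
    if s in {"uniform", "ua"}:
        return AdjacentPairPartition.uniform(I)
    if s in {"independence", "indep", "none"}:
        return AdjacentPairPartition.independence(I)
    if s in {"full", "nua", "all"}:
        return AdjacentPairPartition.full(I)
    groups: list[set[int]] = []
    for token in s.split("|"):
        token = token.strip()
        if not token:
            raise ValueError(f"empty group in partition spec {spec!r}")
        pairs: set[int] = set()
        for item in token.split(","):
            item = item.strip()
            if "-" in item:
                a_s, b_s = item.split("-", 1)
                try:
                    a, b = int(a_s), int(b_s)
                except ValueError as exc:
                    raise ValueError(f"cannot parse pair {item!r} in {spec!r}") from exc
                if b != a + 1:
                    raise ValueError(f"{item!r}: adjacent pairs must be of the form k-(k+1)")
                pairs.add(a)
            else:
                if not item.isdigit() or len(item) < 2:
                    raise ValueError(
                        f"group {item!r} in {spec!r} must be a run of >=2 category digits or 'a-b' pairs"
                    )
                cats = [int(ch) for ch in item]
                for a, b in zip(cats, cats[1:]):
                    if b != a + 1:
                        raise ValueError(f"categories in {item!r} must be consecutive and increasing")
                    pairs.add(a)
        groups.append(pairs)
    return AdjacentPairPartition.from_groups(I, groups)


def as_partition(spec: "str | AdjacentPairPartition", I: int) -> AdjacentPairPartition:
    """Coerce a string or partition object to an ``AdjacentPairPartition`` for scale size I."""
    if isinstance(spec, AdjacentPairPartition):
        if spec.I != I:
            raise ValueError(f"partition is for I={spec.I}, table has I={I}")
        return spec
    return parse_partition(spec, I)
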