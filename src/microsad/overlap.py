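"""Presence/absence species overlap between and among communities.

Presence means count >= 1 — no abundance filtering. The shared
percentage depends on the denominator; three conventions are computed so
either reading of a published overlap figure can be matched:

- ``jaccard`` (default): shared / union
- ``min_relative``: shared / size of the smaller set
- ``relative_to_first``: shared / size of the first set
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .table import OTUTable

__all__ = ["OverlapResult", "shared_fraction", "venn_regions", "pairwise_overlap_matrix", "CONVENTIONS"]

CONVENTIONS = ("jaccard", "min_relative", "relative_to_first")


@dataclass
class OverlapResult:
    """Venn region counts for 2 or 3 species sets."""

    labels: list[str]
    regions: dict[tuple[bool, ...], int]  # membership pattern -> count
    shared_percent: float
    convention: str

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def shared_fraction(a: Iterable, b: Iterable, convention: str = "jaccard") -> float:
    """Percentage of species shared between two presence sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("both species sets are empty")
    inter = len(a & b)
    if convention == "jaccard":
        return 100.0 * inter / len(a | b)
    if convention == "min_relative":
        return 100.0 * inter / min(len(a), len(b))
    if convention == "relative_to_first":
        if not a:
            raise ValueError("first set is empty under relative_to_first")
        return 100.0 * inter / len(a)
    raise ValueError(f"unknown overlap convention {convention!r}")


def venn_regions(
    sets: Sequence[Iterable], labels: Sequence[str] | None = None, convention: str = "jaccard"
) -> OverlapResult:
    """Exact Venn region counts for 2 or 3 species sets.

    Region keys are membership patterns, e.g. ``(True, False, True)`` for
    species present in sets 1 and 3 only. Counts always sum to the size of
    the union. The shared percentage is the full intersection over the
    union (for other conventions use :func:`shared_fraction` pairwise).
    """
    sets = [set(s) for s in sets]
    if len(sets) not in (2, 3):
        raise ValueError(
            "venn_regions supports 2 or 3 sets; use pairwise_overlap_matrix for more"
        )
    labels = list(labels) if labels is not None else [f"set{i+1}" for i in range(len(sets))]
    union = set().union(*sets)
    regions: dict[tuple[bool, ...], int] = {}
    for item in union:
        pattern = tuple(item in s for s in sets)
        regions[pattern] = regions.get(pattern, 0) + 1
    inter = set.intersection(*sets) if sets else set()
    shared = 100.0 * len(inter) / len(union) if union else 0.0
    return OverlapResult(labels=labels, regions=regions, shared_percent=shared, convention="jaccard")


def pairwise_overlap_matrix(table: OTUTable, convention: str = "jaccard") -> pd.DataFrame:
    """Samples × samples matrix of shared-species percentages."""
    ids = table.sample_ids
    presence = {s: table.observed_otus(s) for s in ids}
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for a, b in combinations(ids, 2):
        pct_ab = shared_fraction(presence[a], presence[b], convention)
        mat.loc[a, b] = pct_ab
        if convention == "relative_to_first":
            mat.loc[b, a] = shared_fraction(presence[b], presence[a], convention)
        else:
            mat.loc[b, a] = pct_ab
    return mat
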