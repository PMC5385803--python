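"""Weighted UniFrac distances between communities on a shared phylogeny.

Each branch ``b`` of the rooted tree, with length ``l_b``, separates a
set of tips; ``P_x(b)`` is the fraction of community ``x``'s sequences
belonging to tips below ``b``. The raw weighted UniFrac distance is

    sum_b l_b * |P_a(b) - P_b(b)|

and the normalized variant (default, bounded in [0, 1]) divides by
``sum_b l_b * (P_a(b) + P_b(b))``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alpha import AbundanceVector
from .table import OTUTable
from .tree import PhyloTree

__all__ = ["weighted_unifrac", "unifrac_matrix"]


def _relative_abundances(v: AbundanceVector) -> dict[str, float]:
    if v.species_ids is None:
        raise ValueError("abundance vector needs species ids matching tree tips")
    N = v.N
    return {sid: n / N for sid, n in zip(v.species_ids, v.counts)}


def _check_tips(tree_tips: set[str], *vectors: AbundanceVector) -> None:
    missing = sorted(
        {sid for v in vectors for sid in _relative_abundances(v) if sid not in tree_tips}
    )
    if missing:
        raise ValueError(f"OTUs missing from the tree: {', '.join(missing)}")


def weighted_unifrac(
    tree: PhyloTree, a: AbundanceVector, b: AbundanceVector, normalized: bool = True
) -> float:
    """Weighted UniFrac distance between two communities over one tree."""
    tips = set(tree.tip_labels)
    _check_tips(tips, a, b)
    pa, pb = _relative_abundances(a), _relative_abundances(b)
    raw = 0.0
    denom = 0.0
    for length, below in tree.branch_tip_sets():
        Pa = sum(pa.get(t, 0.0) for t in below)
        Pb = sum(pb.get(t, 0.0) for t in below)
        raw += length * abs(Pa - Pb)
        denom += length * (Pa + Pb)
    if not normalized:
        return raw
    if denom == 0.0:  # both communities concentrated on zero-length branches
        return 0.0
    return raw / denom


def unifrac_matrix(table: OTUTable, tree: PhyloTree, normalized: bool = True) -> pd.DataFrame:
    """All-pairs weighted UniFrac distances for an OTU table.

    Branch tip sets are resolved once and each branch's descendant
    abundance fraction is accumulated per sample, so the pairwise loop is
    a vector operation.
    """
    tips = set(tree.tip_labels)
    vectors = {
        s: AbundanceVector(table.sample_counts(s), species_ids=table.otu_ids)
        for s in table.sample_ids
    }
    _check_tips(tips, *vectors.values())
    branches = tree.branch_tip_sets()
    lengths = np.array([l for l, _ in branches])
    # samples x branches matrix of descendant fractions
    P = np.zeros((table.n_samples, len(branches)))
    for i, s in enumerate(table.sample_ids):
        rel = _relative_abundances(vectors[s])
        for j, (_, below) in enumerate(branches):
            P[i, j] = sum(rel.get(t, 0.0) for t in below)
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.sum(lengths * np.abs(P[i] - P[j]))
            if normalized:
                denom = np.sum(lengths * (P[i] + P[j]))
                d = diff / denom if denom > 0 else 0.0
            else:
                d = diff
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)
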