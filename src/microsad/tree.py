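"""Rooted phylogenetic trees for UniFrac, backed by dendropy.

A ``PhyloTree`` wraps a rooted ``dendropy.Tree`` and enforces what the
weighted UniFrac metric needs: unique tip labels and finite non-negative
branch lengths. Missing branch lengths default to 0 with a warning.
"""

from __future__ import annotations

import warnings
import dendropy

__all__ = ["PhyloTree", "read_newick", "write_newick"]


class PhyloTree:
    """Rooted tree with tip labels and branch lengths ``>= 0``."""

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {', '.join(dupes)}")
        defaulted = False
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue  # root edge carries no length
            if edge.length is None:
                edge.length = 0.0
                defaulted = True
            elif not (edge.length >= 0) or edge.length != edge.length:
                raise ValueError(f"branch length {edge.length!r} is not finite and >= 0")
        if defaulted:
            warnings.warn("missing branch lengths defaulted to 0", stacklevel=3)
        self._tree = tree

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter() if e.tail_node is not None
        )

    def branch_tip_sets(self) -> list[tuple[float, frozenset[str]]]:
        """Per branch: (length, labels of tips descending from it).

        This is the decomposition weighted UniFrac sums over; computed in a
        single postorder pass.
        """
        out: list[tuple[float, frozenset[str]]] = []
        below: dict[int, frozenset[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tips = frozenset([node.taxon.label])
            else:
                tips = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = tips
            if node.parent_node is not None:
                out.append((float(node.edge.length or 0.0), tips))
        return out

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"Newick parse error: {exc}") from exc
        return cls(tree)


def read_newick(path) -> PhyloTree:
    """Read a rooted Newick tree; absent branch lengths default to 0 (warned)."""
    with open(path, "rt", encoding="utf-8") as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(tree.as_newick() + "\n")
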