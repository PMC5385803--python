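"""Weighted UniFrac and PCoA against hand, brute-force and reference oracles."""

import io

import numpy as np
import pandas as pd
import pytest

from microsad import AbundanceVector, OTUTable, pcoa, unifrac_matrix, weighted_unifrac
from microsad.simulate import random_tree
from microsad.tree import PhyloTree


def _vec(mapping):
    ids = list(mapping)
    return AbundanceVector([mapping[i] for i in ids], species_ids=ids)


@pytest.fixture
def cherry_tree():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


class TestWeightedUnifrac:
    def test_identical_communities_distance_zero(self, cherry_tree):
        a = _vec({"A": 2, "B": 2})
        assert weighted_unifrac(cherry_tree, a, a, normalized=False) == pytest.approx(0.0)
        assert weighted_unifrac(cherry_tree, a, a, normalized=True) == pytest.approx(0.0)

    def test_two_leaf_maximal_separation(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        a, b = _vec({"A": 5}), _vec({"B": 3})
        assert weighted_unifrac(tree, a, b, normalized=True) == pytest.approx(1.0)

    def test_hand_oracle_per_branch(self, cherry_tree):
        # branch-by-branch: A 1*|0.5-0| + B 1*|0.5-0| + AB 1*|1-0| + C 2*|0-1| = 4
        a, b = _vec({"A": 2, "B": 2}), _vec({"C": 4})
        assert weighted_unifrac(cherry_tree, a, b, normalized=False) == pytest.approx(4.0)
        assert weighted_unifrac(cherry_tree, a, b, normalized=True) == pytest.approx(1.0)

    def test_missing_otu_reported_by_id(self, cherry_tree):
        with pytest.raises(ValueError, match="ZZ"):
            weighted_unifrac(cherry_tree, _vec({"ZZ": 1}), _vec({"A": 1}))

    def test_agrees_with_tip_enumeration_brute_force(self):
        """Independent oracle: for every branch, recompute the descendant
        proportion by explicit dendropy leaf iteration."""
        rng = np.random.default_rng(99)
        for rep in range(10):
            tree = random_tree(32, seed=1000 + rep)
            tips = tree.tip_labels
            ca = rng.integers(0, 6, size=32)
            cb = rng.integers(0, 6, size=32)
            ca[rng.integers(32)] += 1  # ensure nonempty
            cb[rng.integers(32)] += 1
            a = AbundanceVector(ca, species_ids=tips)
            b = AbundanceVector(cb, species_ids=tips)
            pa = dict(zip(a.species_ids, a.counts / a.N))
            pb = dict(zip(b.species_ids, b.counts / b.N))
            raw = 0.0
            denom = 0.0
            for node in tree.dendropy_tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                below = [leaf.taxon.label for leaf in node.leaf_iter()]
                Pa = sum(pa.get(t, 0.0) for t in below)
                Pb = sum(pb.get(t, 0.0) for t in below)
                raw += node.edge.length * abs(Pa - Pb)
                denom += node.edge.length * (Pa + Pb)
            assert weighted_unifrac(tree, a, b, normalized=False) == pytest.approx(raw, abs=1e-9)
            assert weighted_unifrac(tree, a, b, normalized=True) == pytest.approx(
                raw / denom, abs=1e-9
            )

    def test_agrees_with_reference_implementation(self):
        """Cross-check against scikit-bio on random trees and counts."""
        skbio = pytest.importorskip("skbio")
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        rng = np.random.default_rng(5)
        for rep in range(5):
            tree = random_tree(16, seed=500 + rep)
            tips = tree.tip_labels
            ca = rng.integers(0, 8, size=16)
            cb = rng.integers(0, 8, size=16)
            ca[0] += 1
            cb[-1] += 1
            sk_tree = skbio.TreeNode.read(io.StringIO(tree.as_newick()))
            for normalized in (False, True):
                ours = weighted_unifrac(
                    tree,
                    AbundanceVector(ca, species_ids=tips),
                    AbundanceVector(cb, species_ids=tips),
                    normalized=normalized,
                )
                theirs = skbio_wu(ca, cb, taxa=tips, tree=sk_tree, normalized=normalized)
                assert ours == pytest.approx(float(theirs), abs=1e-9)

    def test_pseudo_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(17)
        tree = random_tree(24, seed=7)
        tips = tree.tip_labels
        vecs = []
        for _ in range(6):
            c = rng.integers(0, 5, size=24)
            c[rng.integers(24)] += 1
            vecs.append(AbundanceVector(c, species_ids=tips))
        for i in range(6):
            for j in range(6):
                dij = weighted_unifrac(tree, vecs[i], vecs[j], normalized=False)
                dji = weighted_unifrac(tree, vecs[j], vecs[i], normalized=False)
                assert dij == pytest.approx(dji, abs=1e-12)
                nij = weighted_unifrac(tree, vecs[i], vecs[j], normalized=True)
                assert -1e-12 <= nij <= 1 + 1e-12
                for k in range(6):
                    dik = weighted_unifrac(tree, vecs[i], vecs[k], normalized=False)
                    dkj = weighted_unifrac(tree, vecs[k], vecs[j], normalized=False)
                    assert dij <= dik + dkj + 1e-9


class TestUnifracMatrix:
    def test_identical_samples_zero_matrix(self, cherry_tree):
        t = OTUTable([[2, 2, 1]] * 3, ["x", "y", "z"], ["A", "B", "C"])
        mat = unifrac_matrix(t, cherry_tree)
        assert np.allclose(mat.to_numpy(), 0.0)

    def test_entries_match_pairwise_calls_and_relabeling(self, gut_dataset):
        t = gut_dataset.table
        # subset to keep the pairwise loop cheap
        keep = t.sample_ids[:4]
        idx = [t.sample_ids.index(s) for s in keep]
        sub = OTUTable(t.counts[idx], keep, t.otu_ids).drop_empty_otus()
        tree = gut_dataset.tree
        mat = unifrac_matrix(sub, tree)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        for i, a in enumerate(keep):
            for b in keep[i + 1 :]:
                va = AbundanceVector(sub.sample_counts(a), species_ids=sub.otu_ids)
                vb = AbundanceVector(sub.sample_counts(b), species_ids=sub.otu_ids)
                assert mat.loc[a, b] == pytest.approx(weighted_unifrac(tree, va, vb), abs=1e-12)
        # permuting sample order permutes the matrix identically
        perm = keep[::-1]
        idx2 = [t.sample_ids.index(s) for s in perm]
        mat2 = unifrac_matrix(OTUTable(t.counts[idx2], perm, t.otu_ids).drop_empty_otus(), tree)
        assert np.allclose(mat2.loc[keep, keep].to_numpy(), mat.to_numpy(), atol=1e-12)


class TestPCoA:
    def test_zero_matrix_has_no_axes(self):
        res = pcoa(np.zeros((3, 3)))
        assert np.allclose(res.eigenvalues, 0)
        assert res.coordinates.shape[1] == 0

    def test_two_samples_hand_oracle(self):
        res = pcoa(pd.DataFrame([[0, 2], [2, 0]], index=["a", "b"], columns=["a", "b"]))
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-12)
        assert sorted(res.coordinates["P1"]) == pytest.approx([-1.0, 1.0], abs=1e-9)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(d)
        positive = res.eigenvalues > 1e-9
        assert positive.sum() == 2
        coords = res.coordinates.to_numpy()
        d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d2, d, atol=1e-9)

    def test_axis_variance_equals_eigenvalue_over_n(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(d)
        n = 6
        for k in range(res.coordinates.shape[1]):
            var = np.var(res.coordinates.iloc[:, k])  # coordinates are centered
            assert var == pytest.approx(res.eigenvalues[k] / n, abs=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        a = pcoa(d).coordinates.to_numpy()
        b = pcoa(d).coordinates.to_numpy()
        assert np.array_equal(a, b)
        for k in range(a.shape[1]):
            assert a[np.argmax(np.abs(a[:, k])), k] > 0

    def test_agrees_with_reference_implementation(self, gut_dataset):
        """Cross-check eigenvalues and coordinate geometry against scikit-bio
        on the synthetic dataset's UniFrac distances."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        t = gut_dataset.table
        mat = unifrac_matrix(t, gut_dataset.tree)
        ours = pcoa(mat)
        theirs = skbio_pcoa(skbio.DistanceMatrix(mat.to_numpy(), ids=mat.index))
        k = ours.coordinates.shape[1]
        assert np.allclose(
            ours.eigenvalues[:k], theirs.eigvals.to_numpy()[:k], atol=1e-8
        )
        # coordinates agree up to per-axis sign
        for axis in range(min(3, k)):
            ref = theirs.samples.to_numpy()[:, axis]
            got = ours.coordinates.to_numpy()[:, axis]
            assert np.allclose(got, ref, atol=1e-6) or np.allclose(got, -ref, atol=1e-6)

    def test_negative_eigenvalues_warned_and_corrections_available(self):
        # non-Euclidean: violates the triangle inequality strongly
        d = np.array(
            [
                [0.0, 1.0, 1.0, 4.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 1.0],
                [4.0, 1.0, 1.0, 0.0],
            ]
        )
        with pytest.warns(UserWarning, match="negative eigenvalues"):
            res = pcoa(d)
        assert res.eigenvalues[-1] < 0
        fixed = pcoa(d, correction="lingoes")
        assert np.all(fixed.eigenvalues >= -1e-8)
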