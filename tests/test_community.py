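"""Beta diversity, ordination and PERMANOVA against independent oracles."""

import io as _io
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import permanova as skbio_permanova

from mgscope.community import bray_curtis, jaccard, pcoa, permanova, unifrac
from mgscope.datamodel import FeatureTable, ValidationError
from mgscope.synth import generate_tree


def _ft(vals, features, samples):
    return FeatureTable(
        values=pd.DataFrame(np.asarray(vals, dtype=float), index=features,
                            columns=samples)
    )


class TestBrayCurtisJaccard:
    def test_identical_columns_zero(self):
        ft = _ft([[1, 1], [2, 2]], ["a", "b"], ["s1", "s2"])
        assert bray_curtis(ft)["s1", "s2"] == 0.0
        assert jaccard(ft)["s1", "s2"] == 0.0

    def test_disjoint_supports_one(self):
        ft = _ft([[0.6, 0], [0.4, 0], [0, 1.0]], ["a", "b", "c"], ["s1", "s2"])
        assert bray_curtis(ft)["s1", "s2"] == pytest.approx(1.0)
        assert jaccard(ft)["s1", "s2"] == pytest.approx(1.0)

    def test_double_loop_oracle(self, rng):
        vals = rng.random((10, 6))
        ft = _ft(vals, [f"f{i}" for i in range(10)], [f"s{j}" for j in range(6)])
        d = bray_curtis(ft)
        for i in range(6):
            for j in range(6):
                u, v = vals[:, i], vals[:, j]
                expect = np.abs(u - v).sum() / (u + v).sum()
                assert d[f"s{i}", f"s{j}"] == pytest.approx(expect, abs=1e-12)


class TestUnifrac:
    HAND_TREE = "((L1:1,L2:1):1,L3:2);"

    def _tree(self, nwk):
        return TreeNode.read(_io.StringIO(nwk))

    def test_hand_worked_three_leaf_example(self):
        # L1 unique to A (1), L2 unique to B (1); shared: internal (1) + L3 (2)
        ft = _ft([[1, 0], [0, 1], [1, 1]], ["L1", "L2", "L3"], ["A", "B"])
        d = unifrac(ft, self._tree(self.HAND_TREE), mode="unweighted")
        assert d["A", "B"] == pytest.approx(0.4)

    def test_identical_communities_zero(self):
        ft = _ft([[1, 1], [2, 2], [3, 3]], ["L1", "L2", "L3"], ["A", "B"])
        for mode in ("unweighted", "weighted_normalized"):
            assert unifrac(ft, self._tree(self.HAND_TREE), mode=mode)["A", "B"] == 0.0

    def test_star_tree_disjoint_is_one(self):
        ft = _ft([[1, 0], [0, 1]], ["L1", "L2"], ["A", "B"])
        star = self._tree("(L1:1,L2:1);")
        for mode in ("unweighted", "weighted_normalized"):
            assert unifrac(ft, star, mode=mode)["A", "B"] == pytest.approx(1.0)

    def test_missing_feature_listed(self):
        ft = _ft([[1, 1]], ["LX"], ["A", "B"])
        with pytest.raises(ValidationError, match="LX"):
            unifrac(ft, self._tree(self.HAND_TREE))

    @pytest.mark.parametrize("mode,skbio_metric", [
        ("unweighted", "unweighted_unifrac"),
        ("weighted_normalized", "weighted_unifrac"),
    ])
    def test_against_skbio_oracle(self, rng, mode, skbio_metric):
        for trial in range(10):
            n_leaves = int(rng.integers(3, 9))
            leaves = [f"t{i}" for i in range(n_leaves)]
            tree = generate_tree(leaves, rng_seed=int(rng.integers(2**31)))
            counts = rng.integers(0, 20, size=(4, n_leaves))
            counts[:, 0] += 1  # no empty samples
            ids = [f"s{i}" for i in range(4)]
            kwargs = {"normalized": True} if mode == "weighted_normalized" else {}
            expect = beta_diversity(
                skbio_metric, counts, ids=ids, taxa=leaves, tree=tree.copy(),
                **kwargs,
            )
            ft = _ft(counts.T, leaves, ids)
            got = unifrac(ft, tree, mode=mode)
            np.testing.assert_allclose(
                np.asarray(got.data), np.asarray(expect.data), atol=1e-10
            )


class TestPcoa:
    def test_points_on_a_line(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(D, ids=["a", "b", "c"]))
        C = res.coordinates.to_numpy()
        recon = np.sqrt(((C[:, None] - C[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, D, atol=1e-9)

    def test_planar_points_reconstructed(self, rng):
        pts = rng.normal(size=(8, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(D, ids=[f"s{i}" for i in range(8)]))
        C = res.coordinates.to_numpy()
        recon = np.sqrt(((C[:, None] - C[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, D, atol=1e-9)
        assert np.abs(res.negative_eigenvalues).sum() <= 1e-8 * res.eigenvalues.sum()

    def test_all_zero_distances(self):
        res = pcoa(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))
        assert res.coordinates.to_numpy().size == 0 or np.allclose(
            res.coordinates.to_numpy(), 0
        )

    def test_proportions_descending_and_bounded(self, rng):
        pts = rng.normal(size=(10, 4))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(D, ids=[f"s{i}" for i in range(10)]))
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.proportion_explained.sum() <= 1 + 1e-9


class TestPermanova:
    def _dm(self, rng, n):
        pts = rng.normal(size=(n, 3))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return DistanceMatrix(D, ids=[f"s{i}" for i in range(n)])

    def test_equal_distances_p_one(self):
        D = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(D, ids=list("abcd"))
        design = pd.Series(["x", "x", "x", "y"], index=list("abcd"))
        res = permanova(dm, design, n_permutations=999, rng_seed=0)
        # all relabelings give the identical F: p must be 1 by enumeration
        assert res.p_value == pytest.approx(1.0)

    def test_exhaustive_enumeration_n4(self, rng):
        dm = self._dm(rng, 4)
        design = pd.Series(["x", "x", "y", "y"], index=dm.ids)
        res = permanova(dm, design, n_permutations=999, rng_seed=3)
        fs = [
            permanova(
                dm,
                pd.Series(np.array(design)[list(p)], index=dm.ids),
                n_permutations=0, rng_seed=0,
            ).pseudo_F
            for p in permutations(range(4))
        ]
        exact = np.mean([f >= res.pseudo_F - 1e-12 for f in fs])
        assert res.p_value == pytest.approx(exact, abs=0.05)

    def test_duplicated_samples_same_r2(self, rng):
        dm = self._dm(rng, 6)
        design = pd.Series(["a", "a", "a", "b", "b", "b"], index=dm.ids)
        r2 = permanova(dm, design, n_permutations=9, rng_seed=0).R2
        D = np.asarray(dm.data)
        D2 = np.block([[D, D], [D, D]])
        np.fill_diagonal(D2, 0)
        dm2 = DistanceMatrix(D2, ids=[f"s{i}" for i in range(12)])
        design2 = pd.Series(list(design) * 2, index=dm2.ids)
        r2_dup = permanova(dm2, design2, n_permutations=9, rng_seed=0).R2
        assert r2_dup == pytest.approx(r2, abs=1e-9)

    def test_label_relabeling_invariance(self, rng):
        dm = self._dm(rng, 8)
        design = pd.Series(["a"] * 4 + ["b"] * 4, index=dm.ids)
        flipped = design.map({"a": "b", "b": "a"})
        a = permanova(dm, design, n_permutations=99, rng_seed=1)
        b = permanova(dm, flipped, n_permutations=99, rng_seed=1)
        assert a.R2 == pytest.approx(b.R2, abs=1e-12)
        assert a.pseudo_F == pytest.approx(b.pseudo_F, abs=1e-9)

    def test_matches_skbio_pseudo_f(self, rng):
        dm = self._dm(rng, 12)
        labels = ["g1"] * 6 + ["g2"] * 6
        design = pd.Series(labels, index=dm.ids)
        ours = permanova(dm, design, n_permutations=99, rng_seed=0)
        theirs = skbio_permanova(dm, grouping=labels, permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_continuous_covariate_runs(self, rng):
        dm = self._dm(rng, 10)
        covar = pd.Series(rng.normal(size=10), index=dm.ids)
        res = permanova(dm, covar, n_permutations=99, rng_seed=0)
        assert 0 <= res.R2 <= 1
        assert 0 < res.p_value <= 1

    def test_collinear_design_rejected(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        design = pd.Series(["x", "x", "x", "x"], index=list("abcd"))
        with pytest.raises(ValidationError):
            permanova(dm, design, n_permutations=9, rng_seed=0)
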