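"""Nonparametric differential tests against enumeration oracles."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from mgscope.datamodel import FeatureTable, ValidationError
from mgscope.differential import (
    bh_adjust,
    kruskal_per_feature,
    paired_two_timepoint,
    wilcoxon_per_feature,
)


def _ft(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return FeatureTable(
        values=pd.DataFrame(rows, index=[f"f{i}" for i in range(rows.shape[0])],
                            columns=samples)
    )


def _groups(labels, ft):
    return pd.Series(labels, index=ft.values.columns)


class TestWilcoxon:
    def test_full_separation_3v3_exact(self):
        """Enumeration oracle: of C(6,3)=20 assignments, 2 are as extreme."""
        ft = _ft([[1, 2, 3, 4, 5, 6]])
        res = wilcoxon_per_feature(ft, _groups(["a"] * 3 + ["b"] * 3, ft))
        pooled = [1, 2, 3, 4, 5, 6]
        obs_sum = 1 + 2 + 3
        count = sum(
            1 for c in combinations(pooled, 3)
            if sum(c) <= obs_sum or sum(c) >= sum(pooled) - obs_sum
        )
        assert res[0].p_value == pytest.approx(count / 20)
        assert res[0].p_value == pytest.approx(0.1)
        assert res[0].direction == "b"

    def test_identical_groups(self):
        ft = _ft([[2, 2, 2, 2, 2, 2]])
        res = wilcoxon_per_feature(ft, _groups(["a"] * 3 + ["b"] * 3, ft))
        assert res[0].p_value == pytest.approx(1.0)
        assert res[0].effect == 0.0

    def test_exact_vs_normal_approx_agree(self, rng):
        """The exact branch and the tie-corrected normal branch agree for 8+8."""
        for _ in range(20):
            vals = np.exp(rng.normal(size=16))
            ft = _ft([vals])
            groups = _groups(["a"] * 8 + ["b"] * 8, ft)
            p_exact = wilcoxon_per_feature(ft, groups)[0].p_value
            from scipy import stats

            p_norm = stats.mannwhitneyu(
                vals[:8], vals[8:], alternative="two-sided", method="asymptotic",
            ).pvalue
            assert p_exact == pytest.approx(p_norm, abs=0.02)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.random(12)
        ft1 = _ft([vals])
        ft2 = _ft([np.exp(5 * vals)])
        g = ["a"] * 6 + ["b"] * 6
        p1 = wilcoxon_per_feature(ft1, _groups(g, ft1))[0].p_value
        p2 = wilcoxon_per_feature(ft2, _groups(g, ft2))[0].p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_small_group_rejected(self):
        ft = _ft([[1, 2, 3]])
        with pytest.raises(ValidationError, match="2 samples"):
            wilcoxon_per_feature(ft, _groups(["a", "a", "b"], ft))

    def test_bh_adjusted_significance(self, rng):
        vals = np.exp(rng.normal(size=(20, 12)))
        ft = _ft(vals)
        res = wilcoxon_per_feature(
            ft, _groups(["a"] * 6 + ["b"] * 6, ft), alpha=0.05, adjust="bh"
        )
        for r in res:
            assert r.adjusted_p >= r.p_value - 1e-12
            assert r.significant == (r.adjusted_p < 0.05)


class TestKruskal:
    def test_constant_feature(self):
        ft = _ft([[3, 3, 3, 3, 3, 3]])
        res = kruskal_per_feature(ft, _groups(["a", "a", "b", "b", "c", "c"], ft))
        assert res[0].statistic == 0.0
        assert res[0].p_value == pytest.approx(1.0)

    def test_hand_computed_h(self):
        """H = 12/(N(N+1)) * sum(R_g^2/n_g) - 3(N+1) on fully separated ranks."""
        ft = _ft([[1, 2, 3, 11, 12, 13, 21, 22, 23]])
        groups = _groups(["a"] * 3 + ["b"] * 3 + ["c"] * 3, ft)
        res = kruskal_per_feature(ft, groups)
        n, k = 9, 3
        rank_sums = [6, 15 + 18 + 12, 24 + 25 + 26]  # ranks 1..9 per group
        rank_sums = [1 + 2 + 3, 4 + 5 + 6, 7 + 8 + 9]
        h = 12 / (n * (n + 1)) * sum(r**2 / 3 for r in rank_sums) - 3 * (n + 1)
        assert res[0].statistic == pytest.approx(h)

    def test_two_level_matches_rank_sum(self, rng):
        vals = np.exp(rng.normal(size=(5, 40)))
        ft = _ft(vals)
        g2 = _groups(["a"] * 20 + ["b"] * 20, ft)
        kr = kruskal_per_feature(ft, g2)
        wc = wilcoxon_per_feature(ft, g2)
        for a, b in zip(kr, wc):
            assert a.p_value == pytest.approx(b.p_value, abs=0.02)


class TestPaired:
    def test_zero_differences(self):
        ft = _ft([[1, 1, 2, 2, 3, 3]])
        pairs = [("s0", "s1"), ("s2", "s3"), ("s4", "s5")]
        res = paired_two_timepoint(ft, pairs)
        assert res[0].p_value == pytest.approx(1.0)

    def test_all_positive_differences_exact(self):
        """Sign-pattern enumeration: 2 of 2^5 patterns reach |W| this extreme."""
        ft = _ft([[1, 2, 1, 3, 2, 4, 3, 7, 1, 6]])
        pairs = [(f"s{2 * i}", f"s{2 * i + 1}") for i in range(5)]
        res = paired_two_timepoint(ft, pairs)
        diffs = [1, 2, 2, 4, 5]
        ranks = [1, 2.5, 2.5, 4, 5]
        obs = sum(ranks)  # all positive: W+ = 15
        count = 0
        for signs in product([1, -1], repeat=5):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            if w_plus >= obs or w_plus <= sum(ranks) - obs:
                count += 1
        assert res[0].p_value == pytest.approx(count / 32)
        assert res[0].p_value == pytest.approx(0.0625)
        assert res[0].direction == "t2"

    def test_rank_sum_method_delegates(self, rng):
        vals = np.exp(rng.normal(size=(3, 10)))
        ft = _ft(vals)
        pairs = [(f"s{2 * i}", f"s{2 * i + 1}") for i in range(5)]
        res_rs = paired_two_timepoint(ft, pairs, method="rank_sum")
        t1 = [p[0] for p in pairs]
        t2 = [p[1] for p in pairs]
        sub = FeatureTable(values=ft.values[t1 + t2])
        direct = wilcoxon_per_feature(
            sub, pd.Series(["t1"] * 5 + ["t2"] * 5, index=t1 + t2), alpha=0.05
        )
        for a, b in zip(res_rs, direct):
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_missing_pair_member(self):
        ft = _ft([[1, 2]], samples=["s0", "s1"])
        with pytest.raises(ValidationError, match="missing"):
            paired_two_timepoint(ft, [("s0", "sX")])


class TestBhAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_order_relation_preserved(self, rng):
        p = rng.uniform(1e-6, 1, size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 0.0])
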