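"""Two-step gene-abundance normalisation and profile aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgscope.abundance import (
    aggregate_by_map,
    best_hit_ko_map,
    compute_copy_numbers,
    normalize_relative,
)
from mgscope.datamodel import FeatureTable, GeneCountMatrix, HitTable, ValidationError

from conftest import random_feature_table


def _gcm(counts, lengths):
    g, s = np.asarray(counts).shape
    return GeneCountMatrix(
        counts=pd.DataFrame(counts, index=[f"g{i}" for i in range(g)],
                            columns=[f"s{j}" for j in range(s)]),
        lengths=pd.Series(lengths, index=[f"g{i}" for i in range(g)]),
    )


class TestCopyNumbers:
    def test_direct_formula(self, tiny_gcm):
        cn = compute_copy_numbers(tiny_gcm)
        assert cn.values.loc["g1", "s1"] == pytest.approx(10 / 100)
        assert cn.values.loc["g1", "s2"] == 0.0
        assert cn.values.loc["g2", "s2"] == pytest.approx(5 / 200)
        assert cn.kind == "copy_number"

    def test_scalar_loop_oracle(self, rng):
        counts = rng.integers(0, 500, size=(12, 7))
        lengths = rng.integers(100, 3000, size=12)
        cn = compute_copy_numbers(_gcm(counts, lengths)).values.to_numpy()
        for i in range(12):
            for j in range(7):
                assert cn[i, j] == counts[i, j] / lengths[i]

    def test_linearity(self, rng):
        counts = rng.integers(0, 500, size=(6, 4))
        lengths = rng.integers(100, 3000, size=6)
        a = compute_copy_numbers(_gcm(counts, lengths)).values.to_numpy()
        b = compute_copy_numbers(_gcm(counts * 2, lengths)).values.to_numpy()
        np.testing.assert_allclose(b, 2 * a, rtol=1e-14)


class TestNormalizeRelative:
    def test_simple_column(self):
        ft = FeatureTable(
            values=pd.DataFrame({"s": [0.1, 0.3]}, index=["a", "b"]),
            kind="copy_number",
        )
        rel = normalize_relative(ft)
        np.testing.assert_allclose(rel.values["s"].to_numpy(), [0.25, 0.75])
        assert rel.kind == "relative"

    def test_zero_column_names_sample(self):
        ft = FeatureTable(
            values=pd.DataFrame({"ok": [1.0, 1.0], "empty": [0.0, 0.0]},
                                index=["a", "b"]),
            kind="copy_number",
        )
        with pytest.raises(ValidationError, match="empty"):
            normalize_relative(ft)

    def test_column_sums_one_random(self, rng):
        for _ in range(50):
            ft = random_feature_table(rng, n_features=int(rng.integers(2, 20)))
            rel = normalize_relative(ft)
            np.testing.assert_allclose(
                rel.values.sum(axis=0).to_numpy(), 1.0, atol=1e-9
            )

    def test_invariant_to_per_sample_scaling(self, rng):
        ft = random_feature_table(rng)
        scaled = FeatureTable(
            values=ft.values * rng.uniform(0.5, 10, size=ft.values.shape[1]),
            kind="copy_number",
        )
        np.testing.assert_allclose(
            normalize_relative(ft).values.to_numpy(),
            normalize_relative(scaled).values.to_numpy(),
            rtol=1e-12,
        )


class TestAggregate:
    def _rel(self, mapping):
        vals = pd.DataFrame({"s": list(mapping.values())}, index=list(mapping))
        return FeatureTable(values=vals, kind="relative")

    def test_bucket_policy(self):
        ft = self._rel({"g1": 0.2, "g2": 0.3, "g3": 0.5})
        out = aggregate_by_map(ft, {"g1": "k1", "g2": "k1"}, "bucket")
        assert out.values.loc["k1", "s"] == pytest.approx(0.5)
        assert out.values.loc["unassigned", "s"] == pytest.approx(0.5)
        assert out.kind == "relative"

    def test_drop_policy(self):
        ft = self._rel({"g1": 0.2, "g2": 0.3, "g3": 0.5})
        out = aggregate_by_map(ft, {"g1": "k1", "g2": "k1"}, "drop")
        assert out.values.index.tolist() == ["k1"]
        assert out.values["s"].sum() == pytest.approx(0.5)

    def test_mass_conservation_random_map(self, rng):
        ft = random_feature_table(rng, n_features=30)
        groups = [f"grp{i}" for i in range(5)]
        mapping = {
            f: groups[int(rng.integers(0, 5))]
            for f in ft.feature_ids
            if rng.random() < 0.7
        }
        out = aggregate_by_map(ft, mapping, "bucket")
        np.testing.assert_allclose(
            out.values.sum(axis=0).to_numpy(),
            ft.values.sum(axis=0).to_numpy(),
            rtol=1e-12,
        )

    def test_empty_map_rejected(self, rng):
        with pytest.raises(ValidationError, match="empty"):
            aggregate_by_map(random_feature_table(rng), {}, "bucket")


class TestBestHitKoMap:
    def _hits(self, rows):
        df = pd.DataFrame(
            rows, columns=["gene_id", "subject_id", "bit_score", "e_value"]
        )
        df["identity"] = 90.0
        df["coverage"] = 90.0
        return HitTable(rows=df)

    def test_highest_bit_score_wins(self):
        hits = self._hits(
            [["g1", "KO1", 80.0, 1e-10], ["g1", "KO2", 70.0, 1e-12]]
        )
        assert best_hit_ko_map(hits) == {"g1": "KO1"}

    def test_bit_score_exactly_60_excluded(self):
        hits = self._hits([["g1", "KO1", 60.0, 1e-10]])
        assert best_hit_ko_map(hits) == {}

    def test_evalue_filter(self):
        hits = self._hits([["g1", "KO1", 100.0, 1e-3]])
        assert best_hit_ko_map(hits) == {}

    def test_tie_breaking_deterministic(self):
        hits = self._hits(
            [["g1", "KO2", 80.0, 1e-10], ["g1", "KO1", 80.0, 1e-10]]
        )
        assert best_hit_ko_map(hits) == {"g1": "KO1"}

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_exhaustive_scan_oracle(self, data):
        n = data.draw(st.integers(1, 20))
        rows = []
        for i in range(n):
            rows.append(
                [
                    f"g{data.draw(st.integers(0, 4))}",
                    f"KO{data.draw(st.integers(0, 5))}",
                    float(data.draw(st.integers(40, 100))),
                    10.0 ** -data.draw(st.integers(0, 20)),
                ]
            )
        hits = self._hits(rows)
        got = best_hit_ko_map(hits, e_max=1e-5, bit_min=60)
        # brute-force oracle: scan every row per gene
        expect = {}
        for gene in {r[0] for r in rows}:
            cand = [
                r for r in rows
                if r[0] == gene and r[3] <= 1e-5 and r[2] > 60
            ]
            if cand:
                cand.sort(key=lambda r: (-r[2], r[3], r[1]))
                expect[gene] = cand[0][1]
        assert got == expect
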