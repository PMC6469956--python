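"""CAG binning, the MGS size filter and rule-based taxonomy."""

import numpy as np
import pandas as pd
import pytest

from mgscope.abundance import compute_copy_numbers
from mgscope.datamodel import CAG, FeatureTable, HitTable, MGSCatalog, ValidationError
from mgscope.mgs import assign_taxonomy, canopy_cluster, filter_mgs, mgs_abundance
from mgscope.synth import SyntheticSpec, generate_community
from mgscope.validation import adjusted_rand_index


def _ft(vals, genes=None):
    vals = np.asarray(vals, dtype=float)
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    return FeatureTable(
        values=pd.DataFrame(vals, index=genes,
                            columns=[f"s{j}" for j in range(vals.shape[1])]),
        kind="copy_number",
    )


class TestCanopyCluster:
    def test_identical_profiles_one_cag(self):
        base = [1.0, 2, 3, 4, 5, 6]
        cags = canopy_cluster(_ft([base, base, base]))
        assert len(cags) == 1
        assert cags[0].n_members == 3

    def test_two_planted_groups_zero_noise(self, rng):
        a = rng.random(8) + 0.1
        b = rng.random(8) + 0.1
        vals = [a, 2 * a, 0.5 * a, b, 3 * b]
        cags = canopy_cluster(_ft(vals))
        got = {frozenset(c.member_gene_ids) for c in cags}
        # brute-force oracle: connected components of the all-pairs
        # correlation graph at the tight threshold
        X = np.asarray(vals)
        C = np.corrcoef(X)
        adj = C >= 0.9
        comps = []
        seen = set()
        for i in range(len(vals)):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(j for j in range(len(vals)) if adj[k, j])
            seen |= comp
            comps.append(frozenset(f"g{j}" for j in comp))
        assert got == set(comps)
        assert len(got) == 2

    def test_min_obs_sets_aside_sparse_genes(self):
        vals = [[1.0, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 7]]
        cags = canopy_cluster(_ft(vals), min_obs=3)
        members = set().union(*(c.member_gene_ids for c in cags))
        assert members == {"g0"}

    def test_partition_disjoint_and_covering(self, rng):
        gcm, _ = generate_community(SyntheticSpec(rng_seed=5, noise_sd=0.2))
        ft = compute_copy_numbers(gcm)
        cags = canopy_cluster(ft)
        all_members = [g for c in cags for g in c.member_gene_ids]
        assert len(all_members) == len(set(all_members))
        clusterable = (ft.values.to_numpy() > 0).sum(axis=1) >= 3
        assert len(all_members) == int(clusterable.sum())

    def test_gene_order_invariance(self, rng):
        gcm, _ = generate_community(
            SyntheticSpec(rng_seed=6, n_species=4, genes_per_species=(5, 15))
        )
        ft = compute_copy_numbers(gcm)
        perm = rng.permutation(len(ft.values))
        shuffled = FeatureTable(values=ft.values.iloc[perm], kind="copy_number")
        a = {frozenset(c.member_gene_ids) for c in canopy_cluster(ft)}
        b = {frozenset(c.member_gene_ids) for c in canopy_cluster(shuffled)}
        assert a == b

    def test_planted_recovery_zero_noise(self):
        spec = SyntheticSpec(rng_seed=7, noise_sd=0.0, count_noise="none")
        gcm, truth = generate_community(spec)
        cags = canopy_cluster(compute_copy_numbers(gcm))
        assign = {g: c.cag_id for c in cags for g in c.member_gene_ids}
        genes = sorted(truth["gene_species"])
        ari = adjusted_rand_index(
            [truth["gene_species"][g] for g in genes],
            [assign.get(g, "none") for g in genes],
        )
        assert ari == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError, match="3 samples"):
            canopy_cluster(_ft([[1.0, 2]]))


class TestFilterMgs:
    def _cags(self, sizes):
        out, offset = [], 0
        for i, n in enumerate(sizes):
            out.append(
                CAG(
                    cag_id=f"c{i}",
                    member_gene_ids=frozenset(f"g{offset + j}" for j in range(n)),
                    profile=pd.Series([1.0, 1, 1]),
                )
            )
            offset += n
        return out

    def test_strict_boundary(self):
        catalog = filter_mgs(self._cags([60, 50, 10]), min_mgs_size=50)
        assert [catalog.is_mgs(c) for c in catalog.cags] == [True, False, False]

    def test_empty_catalog(self):
        assert filter_mgs([], min_mgs_size=50).mgs == []

    def test_random_sizes_scalar_oracle(self, rng):
        for _ in range(30):
            sizes = rng.integers(1, 100, size=int(rng.integers(1, 6)))
            catalog = filter_mgs(self._cags(sizes), min_mgs_size=50)
            assert [catalog.is_mgs(c) for c in catalog.cags] == [
                int(n) > 50 for n in sizes
            ]


class TestAssignTaxonomy:
    def _hit_rows(self, assignments):
        """assignments: list of (gene, genome, identity, coverage, lineage)."""
        return HitTable(
            rows=pd.DataFrame(
                [
                    {
                        "gene_id": g, "subject_id": ref, "identity": idt,
                        "coverage": cov, "bit_score": 200.0, "e_value": 1e-40,
                        "taxon_label": lin,
                    }
                    for g, ref, idt, cov, lin in assignments
                ]
            )
        )

    def _catalog(self, genes):
        cag = CAG(
            cag_id="m1", member_gene_ids=frozenset(genes),
            profile=pd.Series([1.0, 1, 1]),
        )
        return MGSCatalog(cags=[cag], min_mgs_size=len(genes) - 1)

    def test_nine_of_ten_assigns_genome(self):
        genes = [f"g{i}" for i in range(10)]
        rows = [(g, "G", 96.0, 95.0, "Firmicutes;;;;GenusA;Species A") for g in genes[:9]]
        rows.append((genes[9], "H", 96.0, 95.0, "Firmicutes;;;;GenusB;Species B"))
        result = assign_taxonomy(self._catalog(genes), self._hit_rows(rows))
        tax = result.taxonomy["m1"]
        assert tax["assigned_genome"] == "G"
        assert tax["assigned_taxon"] == "Species A"
        assert tax["rank"] == "species"

    def test_identity_below_floor_unassigned(self):
        genes = [f"g{i}" for i in range(10)]
        rows = [(g, "G", 94.0, 95.0, "Firmicutes;;;;GenusA;Species A") for g in genes[:8]]
        result = assign_taxonomy(self._catalog(genes), self._hit_rows(rows))
        assert result.taxonomy["m1"]["assigned_genome"] is None

    def test_rank_fallback_to_genus(self):
        # species labels split 50/50, genus shared: assignment falls back a rank
        genes = [f"g{i}" for i in range(10)]
        rows = [
            (g, f"G{i % 2}", 96.0, 95.0,
             f"Firmicutes;;;;GenusA;Species {i % 2}")
            for i, g in enumerate(genes)
        ]
        result = assign_taxonomy(self._catalog(genes), self._hit_rows(rows))
        tax = result.taxonomy["m1"]
        assert tax["assigned_taxon"] == "GenusA"
        assert tax["rank"] == "genus"

    def test_vote_oracle_random(self, rng):
        for _ in range(30):
            genes = [f"g{i}" for i in range(int(rng.integers(4, 12)))]
            rows = [
                (
                    g, f"G{rng.integers(0, 3)}",
                    float(rng.uniform(90, 100)), float(rng.uniform(80, 100)), "",
                )
                for g in genes
                for _ in range(int(rng.integers(1, 3)))
            ]
            result = assign_taxonomy(self._catalog(genes), self._hit_rows(rows))
            votes = {}
            for g, ref, idt, cov, _ in rows:
                if idt >= 95 and cov >= 90:
                    votes.setdefault(ref, set()).add(g)
            expect = next(
                (r for r in sorted(votes) if len(votes[r]) / len(genes) > 0.8),
                None,
            )
            assert result.taxonomy["m1"]["assigned_genome"] == expect


class TestMgsAbundance:
    def test_median_and_normalisation(self):
        genes = [f"g{i}" for i in range(3)]
        ft = _ft([[0.1, 1.0], [0.3, 2.0], [0.2, 3.0]], genes)
        cag = CAG(cag_id="m1", member_gene_ids=frozenset(genes),
                  profile=pd.Series([0.2, 2.0]))
        catalog = MGSCatalog(cags=[cag], min_mgs_size=2)
        prof = mgs_abundance(catalog, ft)
        # one MGS: relative abundance 1 in every sample
        np.testing.assert_allclose(prof.values.to_numpy(), 1.0)

    def test_profiles_sum_to_one(self, small_bundle):
        ft = compute_copy_numbers(small_bundle["gene_counts"])
        cags = canopy_cluster(ft)
        catalog = filter_mgs(cags, min_mgs_size=10)
        prof = mgs_abundance(catalog, ft)
        np.testing.assert_allclose(prof.values.sum(axis=0).to_numpy(), 1.0, atol=1e-9)
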