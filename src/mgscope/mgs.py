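"""Co-abundance gene group (CAG) binning and metagenomic species (MGS) calling.

Genes whose copy-number profiles co-vary across samples are grouped by a
deterministic canopy-clustering pass: seeds are visited in descending total
abundance, each seed collects all unassigned genes correlated >= ``tight_r``
with its profile, canopy profiles are the per-sample median of members and
membership is re-collected to a fixed point, then canopies whose profiles
correlate >= ``merge_r`` are merged.  Canopies dominated by a single sample
("shadow" canopies, a hallmark of chimeric bins) are discarded.  CAGs with
more than ``min_mgs_size`` member genes are treated as species-level bins
(MGS) and receive rule-based taxonomy from reference alignments: a gene
matches a genome when it has a hit at >= 95% identity over >= 90% of the
gene length, and an MGS is assigned a genome (or a taxon at some rank) when
more than 80% of its genes agree.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .abundance import normalize_relative
from .datamodel import CAG, FeatureTable, HitTable, MGSCatalog, ValidationError

log = logging.getLogger(__name__)

__all__ = ["canopy_cluster", "filter_mgs", "assign_taxonomy", "mgs_abundance", "RANKS"]

#: taxonomic ranks from most to least specific, as stored in lineage strings
RANKS = ("species", "genus", "family", "order", "class", "phylum")

_MAX_RECOLLECT_ROUNDS = 10


def _safe_corr_matrix(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations; zero-variance rows correlate 0 with everything."""
    xc = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc**2).sum(axis=1))
    ok = sd > 0
    xn = np.zeros_like(xc)
    xn[ok] = xc[ok] / sd[ok, None]
    return xn @ xn.T


def _corr_to_profile(x: np.ndarray, profile: np.ndarray) -> np.ndarray:
    pc = profile - profile.mean()
    psd = np.sqrt((pc**2).sum())
    if psd == 0:
        return np.zeros(x.shape[0])
    xc = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc**2).sum(axis=1))
    ok = sd > 0
    out = np.zeros(x.shape[0])
    out[ok] = (xc[ok] @ pc) / (sd[ok] * psd)
    return out


def canopy_cluster(
    ft: FeatureTable,
    tight_r: float = 0.9,
    merge_r: float = 0.97,
    min_obs: int = 3,
    shadow_frac: float = 0.9,
    seed_order: list[str] | None = None,
) -> list[CAG]:
    """Partition genes into CAGs by seeded canopy clustering on Pearson correlation.

    Deterministic given inputs.  Genes observed (value > 0) in fewer than
    ``min_obs`` samples are set aside as unclustered.  Returns CAGs sorted by
    size (descending), ids ``CAG0001``...; every clustered gene belongs to
    exactly one CAG.
    """
    if not 0 < tight_r <= 1 or not 0 < merge_r <= 1:
        raise ValidationError("tight_r and merge_r must lie in (0, 1]")
    if ft.values.shape[1] < 3:
        raise ValidationError("canopy clustering needs at least 3 samples")
    if tight_r > merge_r:
        log.warning("tight_r %.3f > merge_r %.3f is unusual", tight_r, merge_r)

    X = ft.values.to_numpy(dtype=float)
    gene_ids = np.asarray(ft.values.index)
    observed = (X > 0).sum(axis=1) >= min_obs
    X, gene_ids = X[observed], gene_ids[observed]
    if len(gene_ids) == 0:
        return []

    if seed_order is None:
        totals = X.sum(axis=1)
        order = np.lexsort((gene_ids, -totals))
    else:
        pos = {g: i for i, g in enumerate(gene_ids)}
        order = np.array([pos[g] for g in seed_order if g in pos], dtype=int)

    assigned = np.zeros(len(gene_ids), dtype=bool)
    canopies: list[np.ndarray] = []  # arrays of member indices
    for seed in order:
        if assigned[seed]:
            continue
        profile = X[seed]
        members = np.array([seed])
        for _ in range(_MAX_RECOLLECT_ROUNDS):
            pool = np.flatnonzero(~assigned)
            r = _corr_to_profile(X[pool], profile)
            new = pool[r >= tight_r]
            if seed not in new:  # the seed anchors its canopy
                new = np.append(new, seed)
            new = np.sort(new)
            if np.array_equal(new, members):
                break
            members = new
            profile = np.median(X[members], axis=0)
        assigned[members] = True
        canopies.append(members)

    # merge canopies whose median profiles correlate >= merge_r
    profiles = [np.median(X[m], axis=0) for m in canopies]
    merged = True
    while merged and len(canopies) > 1:
        merged = False
        P = _safe_corr_matrix(np.vstack(profiles))
        np.fill_diagonal(P, -np.inf)
        i, j = np.unravel_index(np.argmax(P), P.shape)
        if P[i, j] >= merge_r:
            keep, drop = min(i, j), max(i, j)
            canopies[keep] = np.sort(np.concatenate([canopies[keep], canopies[drop]]))
            del canopies[drop]
            profiles = [np.median(X[m], axis=0) for m in canopies]
            merged = True

    # discard shadow canopies dominated by a single sample
    kept: list[tuple[np.ndarray, np.ndarray]] = []
    for m in canopies:
        profile = np.median(X[m], axis=0)
        total = profile.sum()
        if total > 0 and profile.max() / total > shadow_frac:
            log.info("dropping shadow canopy of %d genes", len(m))
            continue
        kept.append((m, profile))

    kept.sort(key=lambda mp: (-len(mp[0]), str(gene_ids[mp[0][0]])))
    samples = ft.values.columns
    return [
        CAG(
            cag_id=f"CAG{k + 1:04d}",
            member_gene_ids=frozenset(gene_ids[m]),
            profile=pd.Series(profile, index=samples),
        )
        for k, (m, profile) in enumerate(kept)
    ]


def filter_mgs(cags: list[CAG], min_mgs_size: int = 50) -> MGSCatalog:
    """Flag CAGs with strictly more than ``min_mgs_size`` genes as MGS."""
    return MGSCatalog(cags=list(cags), min_mgs_size=min_mgs_size)


def _passing_best_hits(hits: HitTable, id_min: float, cov_min: float) -> pd.DataFrame:
    df = hits.rows
    passing = df[(df["identity"] >= id_min) & (df["coverage"] >= cov_min)]
    if passing.empty:
        return passing
    ranked = passing.sort_values(
        by=["bit_score", "e_value", "subject_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return ranked.drop_duplicates(subset="gene_id", keep="first")


def assign_taxonomy(
    catalog: MGSCatalog,
    hits: HitTable,
    id_min: float = 95.0,
    cov_min: float = 90.0,
    vote_frac: float = 0.8,
) -> MGSCatalog:
    """Assign genome and rank-level taxonomy to each MGS by majority vote.

    A gene matches genome G when it has >= 1 hit to G at identity >=
    ``id_min`` and coverage >= ``cov_min``; the MGS is assigned G when more
    than ``vote_frac`` of its member genes match G (unique for vote_frac >=
    0.5).  Independently, walking ranks from species to phylum, the first
    rank at which more than ``vote_frac`` of genes share one label is
    assigned.  Lineages come from each gene's best passing hit
    ("phylum;class;order;family;genus;species").
    """
    df = hits.rows
    mgs_genes = set().union(*(c.member_gene_ids for c in catalog.mgs)) if catalog.mgs else set()
    orphan = (~df["gene_id"].isin(mgs_genes)).sum()
    if orphan:
        log.info("%d hit rows reference genes outside any MGS; ignored", orphan)

    passing = df[(df["identity"] >= id_min) & (df["coverage"] >= cov_min)]
    best = _passing_best_hits(hits, id_min, cov_min)
    best_lineage = dict(zip(best["gene_id"], best["taxon_label"]))
    gene_genomes = passing.groupby("gene_id")["subject_id"].agg(set)

    taxonomy: dict[str, dict] = {}
    for cag in catalog.mgs:
        n = cag.n_members
        entry = {"assigned_genome": None, "assigned_taxon": None, "rank": None}
        # genome vote: count genes matching each genome
        votes: dict[str, int] = {}
        for g in cag.member_gene_ids:
            for genome in gene_genomes.get(g, ()):  # type: ignore[arg-type]
                votes[genome] = votes.get(genome, 0) + 1
        for genome in sorted(votes):
            if votes[genome] / n > vote_frac:
                entry["assigned_genome"] = genome
                break
        # rank vote from best-hit lineages, most specific rank first
        lineages = [
            str(best_lineage[g]).split(";")
            for g in cag.member_gene_ids
            if g in best_lineage and best_lineage[g]
        ]
        for depth, rank in enumerate(RANKS):
            labels: dict[str, int] = {}
            for lin in lineages:
                if len(lin) > depth and lin[-1 - depth]:
                    lab = lin[-1 - depth]
                    labels[lab] = labels.get(lab, 0) + 1
            winner = next(
                (lab for lab in sorted(labels) if labels[lab] / n > vote_frac), None
            )
            if winner is not None:
                entry["assigned_taxon"] = winner
                entry["rank"] = rank
                break
        taxonomy[cag.cag_id] = entry
    return MGSCatalog(
        cags=catalog.cags, min_mgs_size=catalog.min_mgs_size, taxonomy=taxonomy
    )


def mgs_abundance(catalog: MGSCatalog, ft: FeatureTable) -> FeatureTable:
    """Relative MGS profile: per-sample median of member copy numbers, renormalised."""
    rows, ids = [], []
    for cag in catalog.mgs:
        members = sorted(cag.member_gene_ids)
        missing = [g for g in members if g not in ft.values.index]
        if missing:
            raise ValidationError(
                f"MGS {cag.cag_id!r} members absent from table: {missing[:5]}"
            )
        rows.append(ft.values.loc[members].median(axis=0))
        ids.append(cag.cag_id)
    if not rows:
        raise ValidationError("catalog contains no MGS")
    raw = pd.DataFrame(rows, index=ids)
    if (raw.to_numpy().sum(axis=1) == 0).all():
        raise ValidationError("all MGS signals are zero in every sample")
    return normalize_relative(FeatureTable(values=raw, kind="copy_number"))
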