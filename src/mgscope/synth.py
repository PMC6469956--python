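"""Seeded synthetic-data generator with planted ground truth.

Emulates the study design end to end: a two-group (control vs PCOS-like)
shotgun cohort whose gene counts arise from planted species with known gene
membership, a KO/pathway layer with planted between-group pathway shifts,
clinical variables with planted monotone couplings to species abundances,
and a longitudinal probiotic-intake arm with responder/non-responder
colonization trajectories read out through a configured qPCR standard
curve.  Every generated bundle carries its ground truth alongside; no
pipeline stage reads the truth.

Generative model for the community: species ``k`` has a latent per-sample
loading ``A[k,s] = exp(species_log_sd * N(0,1))`` scaled by a group effect
for the planted differential species; gene ``g`` of species ``k`` has
expected count ``A[k,s] * L_g * c_s`` (``c_s`` a depth scalar) times
per-gene-per-sample multiplicative lognormal noise of sd ``noise_sd``, and
observed counts are Poisson (or rounded expectations when
``count_noise='none'``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datamodel import (
    FeatureTable,
    GeneCountMatrix,
    HitTable,
    PathwayHierarchy,
    SampleMetadata,
    ValidationError,
)
from .qpcr import StandardCurve

__all__ = [
    "SyntheticSpec",
    "generate_community",
    "generate_ko_layer",
    "generate_clinical",
    "generate_longitudinal",
    "generate_tree",
    "generate_hits",
    "generate_standard_points",
    "generate_bundle",
    "TABLE1_ANCHORS",
]

#: pooled clinical anchor points (mean, sd) used to place synthetic
#: variables on plausible unit scales (mmol/liter, IU/liter, pg/ml, ...)
TABLE1_ANCHORS: dict[str, tuple[float, float]] = {
    "TG": (1.43, 0.24), "TC": (4.40, 0.28), "FPG": (5.76, 0.44),
    "ghrelin": (0.40, 0.03), "PYY": (69.31, 13.18),
    "LH": (12.59, 3.15), "FSH": (5.85, 1.00), "LH/FSH": (2.10, 0.61),
    "E2": (54.57, 10.55), "PRL": (10.51, 1.49), "T": (3.43, 0.72),
    "acetic_acid": (40.98, 9.14), "propionic_acid": (17.04, 4.90),
    "butyric_acid": (8.96, 2.90), "valeric_acid": (1.11, 0.47),
}

#: default monotone couplings: (variable, species index, direction, noise sd)
DEFAULT_COUPLINGS: tuple[tuple[str, int, int, float], ...] = (
    ("acetic_acid", 0, +1, 0.5),
    ("butyric_acid", 0, +1, 0.5),
    ("PYY", 0, +1, 0.5),
    ("LH", 0, -1, 0.5),
    ("propionic_acid", 1, +1, 0.5),
    ("valeric_acid", 1, +1, 0.5),
    ("ghrelin", 1, +1, 0.5),
    ("T", 1, -1, 0.5),
)


@dataclass
class SyntheticSpec:
    """Study conditions for the generator; defaults mirror the cohort design."""

    n_control: int = 20  # shotgun-sequenced subjects per group
    n_case: int = 20
    n_species: int = 10
    genes_per_species: tuple[int, int] = (20, 100)
    depth: float = 1e5  # expected mapped reads per sample
    species_log_sd: float = 1.0  # spread of species loadings across samples
    noise_sd: float = 0.1  # gene-level multiplicative lognormal sd
    count_noise: str = "poisson"  # "poisson" or "none"
    gene_length_range: tuple[int, int] = (300, 3000)
    n_kos: int = 200
    n_pathways: int = 20
    pathway_size: int = 20
    n_planted_pathways: int = 2
    planted_pathway_effect: float = 4.0  # group fold change of shifted species
    down_species: tuple[int, ...] = (0, 1)  # depleted in the case group
    up_species: tuple[int, ...] = (2, 3)  # enriched in the case group
    clinical_couplings: tuple[tuple[str, int, int, float], ...] = DEFAULT_COUPLINGS
    n_subjects_longitudinal: int = 14
    responder_fraction: float = 9 / 14
    colonization_mean: float = 6.93  # log CFU/g in responders
    colonization_sd: float = 0.42
    detection_floor: float = 2.0  # log CFU/g
    curve_slope: float = -3.3219
    curve_intercept: float = 37.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ValidationError("rng_seed is mandatory")
        if not 0 <= self.responder_fraction <= 1:
            raise ValidationError("responder_fraction must lie in [0,1]")
        if self.count_noise not in ("poisson", "none"):
            raise ValidationError(f"unknown count_noise {self.count_noise!r}")

    def streams(self, n: int = 8) -> list[np.random.Generator]:
        """Independent per-component RNG streams derived from the seed."""
        seqs = np.random.SeedSequence(self.rng_seed).spawn(n)
        return [np.random.default_rng(s) for s in seqs]


def _species_effects(spec: SyntheticSpec) -> np.ndarray:
    eff = np.ones(spec.n_species)
    e = spec.planted_pathway_effect
    for k in spec.down_species:
        eff[k] = 1.0 / e
    for k in spec.up_species:
        eff[k] = e
    return eff


def generate_community(spec: SyntheticSpec):
    """Planted two-group gene count matrix.

    Returns ``(GeneCountMatrix, truth)`` where ``truth`` holds the gene ->
    species partition, the species-by-sample latent abundance matrix, the
    per-sample group labels and the species group-effect vector.
    """
    rng = spec.streams()[0]
    samples = [f"C{i + 1:03d}" for i in range(spec.n_control)] + [
        f"P{i + 1:03d}" for i in range(spec.n_case)
    ]
    group = np.array(["control"] * spec.n_control + ["case"] * spec.n_case)
    n_samples = len(samples)

    lo, hi = spec.genes_per_species
    n_genes_per = rng.integers(lo, hi + 1, size=spec.n_species)
    gene_ids, gene_species = [], []
    for k in range(spec.n_species):
        for g in range(n_genes_per[k]):
            gene_ids.append(f"S{k:02d}_g{g + 1:04d}")
            gene_species.append(k)
    gene_species = np.array(gene_species)
    lengths = rng.integers(
        spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=len(gene_ids)
    )

    # latent species loadings: the planted co-abundance profiles
    A = np.exp(spec.species_log_sd * rng.standard_normal((spec.n_species, n_samples)))
    effects = _species_effects(spec)
    A[:, group == "case"] *= effects[:, None]

    expected = A[gene_species] * lengths[:, None].astype(float)
    if spec.noise_sd > 0:
        noise = np.exp(
            spec.noise_sd * rng.standard_normal(expected.shape) - spec.noise_sd**2 / 2
        )
        expected = expected * noise
    # depth scalar per sample so column sums land near the target depth
    expected = expected * (spec.depth / expected.sum(axis=0))
    counts = (
        rng.poisson(expected) if spec.count_noise == "poisson" else np.round(expected)
    ).astype(float)

    gcm = GeneCountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        lengths=pd.Series(lengths, index=gene_ids),
    )
    truth = {
        "gene_species": dict(zip(gene_ids, (f"species_{k}" for k in gene_species))),
        "species_abundance": pd.DataFrame(
            A, index=[f"species_{k}" for k in range(spec.n_species)], columns=samples
        ),
        "group": pd.Series(group, index=samples),
        "species_effects": pd.Series(
            effects, index=[f"species_{k}" for k in range(spec.n_species)]
        ),
    }
    return gcm, truth


def generate_ko_layer(spec: SyntheticSpec, truth: dict):
    """KO map and pathway hierarchy with planted differential pathways.

    Planted pathways take member KOs hosted by the case-enriched species, so
    the planted between-group shift propagates to their KO profiles;
    non-planted pathways draw member KOs uniformly from the full KO pool.
    Returns ``(gene -> KO map, PathwayHierarchy, planted pathway ids)``.
    """
    rng = spec.streams()[1]
    n_planted_kos = spec.n_planted_pathways * spec.pathway_size
    if n_planted_kos > spec.n_kos:
        raise ValidationError("planted pathways need more KOs than n_kos provides")
    kos = [f"K{i + 1:05d}" for i in range(spec.n_kos)]
    host = np.empty(spec.n_kos, dtype=int)
    shifted = list(spec.up_species) or list(range(spec.n_species))
    host[:n_planted_kos] = rng.choice(shifted, size=n_planted_kos)
    host[n_planted_kos:] = rng.integers(0, spec.n_species, size=spec.n_kos - n_planted_kos)

    kos_of_species: dict[int, list[str]] = {k: [] for k in range(spec.n_species)}
    for ko, h in zip(kos, host):
        kos_of_species[h].append(ko)

    gene_ko: dict[str, str] = {}
    by_species: dict[str, list[str]] = {}
    for gene, sp in truth["gene_species"].items():
        by_species.setdefault(sp, []).append(gene)
    for sp, genes in by_species.items():
        k = int(sp.split("_")[1])
        hosted = kos_of_species[k]
        if not hosted:
            continue
        # round-robin keeps KO coverage maximal when genes >= hosted KOs
        for i, gene in enumerate(genes):
            gene_ko[gene] = hosted[i % len(hosted)]

    # pathways reference only KOs some gene actually maps to
    used = set(gene_ko.values())
    planted_pool = [k for k in kos[:n_planted_kos] if k in used]
    all_pool = [k for k in kos if k in used]
    pathways: dict[str, tuple[str, str, frozenset[str]]] = {}
    planted_ids = []
    for p in range(spec.n_pathways):
        pid = f"path{p + 1:03d}"
        if p < spec.n_planted_pathways:
            want = planted_pool[p * spec.pathway_size : (p + 1) * spec.pathway_size]
            if not want:  # tiny communities: fall back to whatever planted KOs exist
                want = planted_pool[: spec.pathway_size]
            members = want
            planted_ids.append(pid)
            level2 = "planted"
        else:
            members = list(
                rng.choice(all_pool, size=min(spec.pathway_size, len(all_pool)), replace=False)
            )
            level2 = "background"
        if members:
            pathways[pid] = (f"synthetic pathway {p + 1}", level2, frozenset(members))
    return gene_ko, PathwayHierarchy(pathways=pathways), planted_ids


def generate_clinical(spec: SyntheticSpec, truth: dict) -> SampleMetadata:
    """Clinical variables with planted monotone couplings to species abundances.

    Coupled variables are ``anchor_mean + anchor_sd * (dir*z_k + eps) /
    sqrt(1 + noise_sd^2)`` with ``z_k`` the standardised log abundance of the
    coupled species; uncoupled variables are pure anchored noise and carry
    no group signal (they are the specificity controls for the network
    stage).  Values are floored at 0 to respect measurement units.
    """
    rng = spec.streams()[2]
    abund = truth["species_abundance"]
    samples = abund.columns
    group = truth["group"]
    logA = np.log(abund.to_numpy())
    z = (logA - logA.mean(axis=1, keepdims=True)) / logA.std(axis=1, keepdims=True)

    table = pd.DataFrame(
        {
            "subject_id": [f"subj_{s}" for s in samples],
            "group": group.loc[samples].to_numpy(),
            "timepoint": "week0",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    coupled = {v for v, *_ in spec.clinical_couplings}
    for var, (mean, sd) in TABLE1_ANCHORS.items():
        spec_row = next((c for c in spec.clinical_couplings if c[0] == var), None)
        if spec_row is not None:
            _, k, direction, noise_sd = spec_row
            eps = noise_sd * rng.standard_normal(len(samples))
            raw = (direction * z[k] + eps) / np.sqrt(1 + noise_sd**2)
        else:
            raw = rng.standard_normal(len(samples))
        table[var] = np.maximum(mean + sd * raw, 0.0)
    md = SampleMetadata(table=table, group_levels=("control", "case"))
    md.coupled_variables = sorted(coupled)  # type: ignore[attr-defined]
    return md


def generate_tree(labels: list[str], rng_seed: int = 0) -> TreeNode:
    """Random bifurcating coalescent-style tree over the given leaf labels."""
    rng = np.random.default_rng(rng_seed)
    nodes = [TreeNode(name=lab, length=float(rng.exponential(1.0))) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right], length=float(rng.exponential(0.5)))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


_LINEAGE_POOL = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")


def generate_hits(
    spec: SyntheticSpec,
    truth: dict,
    gene_lengths: pd.Series,
    frac_correct: float = 0.95,
) -> HitTable:
    """Reference-genome alignment hits consistent with the planted partition.

    Each gene hits its own species' genome at high identity/coverage with
    probability ``frac_correct``, and a degraded off-target hit otherwise;
    lineages are placeholder labels "phylum;class;order;family;genus;species".
    """
    rng = spec.streams()[3]
    rows = []
    for gene, sp in truth["gene_species"].items():
        k = int(sp.split("_")[1])
        correct = rng.random() < frac_correct
        target = k if correct else int(rng.integers(0, spec.n_species))
        identity = rng.uniform(96, 100) if correct else rng.uniform(70, 94.9)
        coverage = rng.uniform(92, 100) if correct else rng.uniform(40, 89.9)
        L = float(gene_lengths[gene])
        phylum = _LINEAGE_POOL[target % len(_LINEAGE_POOL)]
        lineage = (
            f"{phylum};class_{target % 3};order_{target % 4};family_{target % 5};"
            f"genus_{target // 2};Species {target}"
        )
        aln = coverage / 100 * L
        rows.append(
            {
                "gene_id": gene, "subject_id": f"genome_{target}",
                "identity": identity, "aln_len": aln,
                "mismatches": int(aln * (100 - identity) / 100), "gaps": 0,
                "qstart": 1, "qend": int(aln), "sstart": 1, "send": int(aln),
                "e_value": 10.0 ** -rng.uniform(20, 80),
                "bit_score": rng.uniform(80, 500),
                "coverage": coverage, "taxon_label": lineage,
            }
        )
    return HitTable(rows=pd.DataFrame(rows))


def generate_standard_points(
    spec: SyntheticSpec, n_points: int = 7, ct_noise_sd: float = 0.15
) -> list[tuple[float, float]]:
    """Dilution-series standards (log10 copies, Ct) around the configured curve."""
    rng = spec.streams()[4]
    xs = np.arange(1, n_points + 1, dtype=float)
    return [
        (float(x), spec.curve_slope * x + spec.curve_intercept
         + float(rng.normal(0, ct_noise_sd)))
        for x in xs
    ]


TIMEPOINTS = ("A", "B", "C", "D", "E", "F", "G")


def generate_longitudinal(spec: SyntheticSpec):
    """Probiotic-intake arm: Ct tables plus responder/non-responder metadata.

    Responders colonize at ``Normal(colonization_mean, colonization_sd)`` log
    CFU/g through consumption (B, D, F) and washout (C, E, G) points;
    non-responders stay at the detection floor plus half-normal jitter; every
    subject starts at the floor at baseline (A).  Ct values are back-computed
    through the configured standard curve.  Responder clinical trajectories
    carry a monotone LH decline and SCFA (acetic acid) rise from week 0 to
    week 10.  Returns ``(ct_series, SampleMetadata, truth_log_cfu)``.
    """
    rng = spec.streams()[5]
    n = spec.n_subjects_longitudinal
    n_resp = int(round(spec.responder_fraction * n))
    subjects = [f"V{i + 1:02d}" for i in range(n)]
    groups = {s: ("R" if i < n_resp else "N") for i, s in enumerate(subjects)}
    curve = StandardCurve(
        slope=spec.curve_slope,
        intercept=spec.curve_intercept,
        r_squared=1.0,
        efficiency=(10 ** (-1 / spec.curve_slope) - 1) * 100,
    )

    week_of = {"A": 0, "B": 2, "C": 2, "D": 4, "E": 4, "F": 10, "G": 10}
    rows, cts, truth_log = [], {}, {}
    for subj in subjects:
        responder = groups[subj] == "R"
        lh0 = rng.normal(18, 2)
        scfa0 = rng.normal(25, 4)
        for tp in TIMEPOINTS:
            sid = f"{subj}_{tp}"
            if tp == "A":
                log_cfu = spec.detection_floor
            elif responder:
                log_cfu = rng.normal(spec.colonization_mean, spec.colonization_sd)
            else:
                log_cfu = spec.detection_floor + abs(rng.normal(0, 0.3))
            truth_log[sid] = log_cfu
            cts[sid] = curve.ct_of(log_cfu)
            frac = week_of[tp] / 10
            if responder:
                lh = lh0 - 10 * frac + rng.normal(0, 0.5)
                scfa = scfa0 + 30 * frac + rng.normal(0, 1.5)
            else:
                lh = lh0 + rng.normal(0, 0.5)
                scfa = scfa0 + rng.normal(0, 1.5)
            rows.append(
                {
                    "sample_id": sid, "subject_id": subj, "group": groups[subj],
                    "timepoint": tp, "LH": max(lh, 0.1), "acetic_acid": max(scfa, 0.1),
                }
            )
    md = SampleMetadata(
        table=pd.DataFrame(rows).set_index("sample_id"), group_levels=("R", "N")
    )
    return pd.Series(cts, name="ct"), md, pd.Series(truth_log, name="log_cfu_per_gram")


def generate_bundle(spec: SyntheticSpec) -> dict:
    """Generate every input the pipeline consumes, with ground truth attached."""
    gcm, truth = generate_community(spec)
    ko_map, hierarchy, planted = generate_ko_layer(spec, truth)
    clinical = generate_clinical(spec, truth)
    hits = generate_hits(spec, truth, gcm.lengths)
    tree = generate_tree(
        list(truth["species_abundance"].index), rng_seed=spec.rng_seed + 11
    )
    sa = truth["species_abundance"]
    genus = FeatureTable(values=sa / sa.to_numpy().sum(axis=0), kind="relative")
    standards = generate_standard_points(spec)
    ct, long_md, truth_log = generate_longitudinal(spec)
    return {
        "spec": spec,
        "gene_counts": gcm,
        "ko_map": ko_map,
        "pathways": hierarchy,
        "clinical": clinical,
        "hits": hits,
        "tree": tree,
        "genus_table": genus,
        "standards": standards,
        "longitudinal_ct": ct,
        "longitudinal_metadata": long_md,
        "truth": {
            **truth,
            "planted_pathways": planted,
            "log_cfu": truth_log,
        },
    }


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Copy of ``spec`` with a new RNG seed."""
    return replace(spec, rng_seed=seed)
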