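"""End-to-end orchestration: simulate -> abundance -> MGS -> stats -> networks -> qPCR.

One YAML (or dict) config drives every stage; all randomness flows from the
config seed, so a rerun with the same config reproduces byte-identical
outputs, recorded in a manifest of SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import abundance, community, differential, io, mgs, networks, qpcr, reporter
from .datamodel import ValidationError
from .synth import SyntheticSpec, generate_bundle

log = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]

STAGES = (
    "simulate", "abundance", "bin_mgs", "community",
    "differential", "reporter", "network", "qpcr",
)


def default_config(out_dir: str, seed: int = 0) -> dict:
    return {
        "out_dir": out_dir,
        "rng_seed": seed,
        "stages": {s: True for s in STAGES},
        "synthetic": {},  # overrides for SyntheticSpec fields
        "canopy": {"tight_r": 0.9, "merge_r": 0.97, "min_obs": 3, "shadow_frac": 0.9},
        "mgs": {"min_mgs_size": 50, "id_min": 95.0, "cov_min": 90.0, "vote_frac": 0.8},
        "beta": {"metric": "unifrac", "mode": "weighted_normalized"},
        "adonis": {"n_permutations": 999},
        "diff": {"alpha": 0.01, "adjust": "none"},
        "reporter": {"n_background": 1000, "threshold": 2.3},
        "network": {"threshold": 0.4, "min_pairs": 5},
        "qpcr": {"grams_assayed": 1.0, "dilution_factor": 1.0, "cfu_per_copy": 1.0},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    ``config`` is a dict or a path to a YAML file shaped like
    :func:`default_config`.  Outputs land under ``out_dir``; the manifest
    (parameters, per-stage outputs with checksums and row counts) is written
    to ``out_dir/manifest.json``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    base = default_config(config.get("out_dir", "."), config.get("rng_seed", 0))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            base[key].update(val)
        else:
            base[key] = val
    cfg = base
    out = io.ensure_dir(cfg["out_dir"])
    enabled = cfg["stages"]
    if any(enabled.values()) and cfg.get("rng_seed") is None:
        raise ValidationError("rng_seed must be set when stochastic stages run")

    manifest: dict = {"parameters": {k: v for k, v in cfg.items() if k != "stages"},
                      "stages": {}}
    state: dict = {}

    def record(stage: str, outputs: dict[str, Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in outputs.items()
            },
            "seconds": round(time.monotonic() - t0, 3),
        }
        log.info("stage %s done in %.2fs", stage, time.monotonic() - t0)

    try:
        if enabled.get("simulate"):
            t0 = time.monotonic()
            spec = SyntheticSpec(rng_seed=cfg["rng_seed"], **cfg["synthetic"])
            bundle = generate_bundle(spec)
            state["bundle"] = bundle
            truth_dir = io.ensure_dir(out / "truth")
            outputs = {}
            io.write_feature_table(
                abundance.compute_copy_numbers(bundle["gene_counts"]),
                out / "gene_copy_number.tsv",
            )
            bundle["gene_counts"].counts.to_csv(out / "gene_counts.tsv", sep="\t")
            bundle["gene_counts"].lengths.to_frame("length").to_csv(
                out / "gene_lengths.tsv", sep="\t"
            )
            io.write_ko_map(bundle["ko_map"], out / "gene_ko_map.tsv")
            io.write_pathways(bundle["pathways"], out / "pathways.tsv")
            io.write_metadata(bundle["clinical"], out / "clinical.csv")
            io.write_hit_table(bundle["hits"], out / "hits.tsv")
            io.write_tree(bundle["tree"], out / "species_tree.nwk")
            io.write_feature_table(bundle["genus_table"], out / "genus_table.tsv")
            bundle["longitudinal_ct"].to_frame().to_csv(out / "qpcr_ct.csv")
            io.write_metadata(bundle["longitudinal_metadata"], out / "longitudinal.csv")
            pd.Series(bundle["truth"]["gene_species"]).to_frame("species").to_csv(
                truth_dir / "gene_species.tsv", sep="\t"
            )
            manifest["parameters"]["synthetic_resolved"] = asdict(spec)
            outputs = {
                name: out / name
                for name in (
                    "gene_counts.tsv", "gene_lengths.tsv", "gene_copy_number.tsv",
                    "gene_ko_map.tsv", "pathways.tsv", "clinical.csv", "hits.tsv",
                    "species_tree.nwk", "genus_table.tsv", "qpcr_ct.csv",
                    "longitudinal.csv",
                )
            }
            outputs["truth/gene_species.tsv"] = truth_dir / "gene_species.tsv"
            record("simulate", outputs, t0)

        if enabled.get("abundance"):
            t0 = time.monotonic()
            gcm = state["bundle"]["gene_counts"] if "bundle" in state else io.read_gene_counts(
                cfg["gene_counts"], cfg["gene_lengths"]
            )
            copy = abundance.compute_copy_numbers(gcm)
            rel = abundance.normalize_relative(copy)
            ko_map = (
                state["bundle"]["ko_map"] if "bundle" in state else io.read_ko_map(cfg["ko_map"])
            )
            ko_table = abundance.aggregate_by_map(rel, ko_map, unmapped_policy="bucket")
            state.update(copy=copy, rel=rel, ko_table=ko_table, gcm=gcm)
            io.write_feature_table(rel, out / "gene_relative.tsv")
            io.write_feature_table(ko_table, out / "ko_relative.tsv")
            record(
                "abundance",
                {"gene_relative.tsv": out / "gene_relative.tsv",
                 "ko_relative.tsv": out / "ko_relative.tsv"},
                t0,
            )

        if enabled.get("bin_mgs"):
            t0 = time.monotonic()
            cags = mgs.canopy_cluster(state["copy"], **cfg["canopy"])
            catalog = mgs.filter_mgs(cags, min_mgs_size=cfg["mgs"]["min_mgs_size"])
            hits = state["bundle"]["hits"] if "bundle" in state else io.read_hit_table(
                cfg["hits"], state["gcm"].lengths
            )
            catalog = mgs.assign_taxonomy(
                catalog, hits,
                id_min=cfg["mgs"]["id_min"], cov_min=cfg["mgs"]["cov_min"],
                vote_frac=cfg["mgs"]["vote_frac"],
            )
            state["catalog"] = catalog
            membership = pd.DataFrame(
                [(g, c.cag_id) for c in cags for g in sorted(c.member_gene_ids)],
                columns=["gene_id", "cag_id"],
            )
            membership.to_csv(out / "cag_membership.tsv", sep="\t", index=False)
            tax = pd.DataFrame.from_dict(catalog.taxonomy, orient="index")
            tax.index.name = "cag_id"
            tax.to_csv(out / "mgs_taxonomy.tsv", sep="\t")
            outputs = {
                "cag_membership.tsv": out / "cag_membership.tsv",
                "mgs_taxonomy.tsv": out / "mgs_taxonomy.tsv",
            }
            if catalog.mgs:
                profile = mgs.mgs_abundance(catalog, state["copy"])
                state["mgs_profile"] = profile
                io.write_feature_table(profile, out / "mgs_profile.tsv")
                outputs["mgs_profile.tsv"] = out / "mgs_profile.tsv"
            record("bin_mgs", outputs, t0)

        if enabled.get("community"):
            t0 = time.monotonic()
            genus = (
                state["bundle"]["genus_table"]
                if "bundle" in state
                else io.read_feature_table(cfg["genus_table"], kind="relative")
            )
            tree = state["bundle"]["tree"] if "bundle" in state else io.read_tree(cfg["tree"])
            dm_w = community.unifrac(genus, tree, mode="weighted_normalized")
            dm_u = community.unifrac(genus, tree, mode="unweighted")
            ord_res = community.pcoa(dm_w, n_axes=2)
            meta = (
                state["bundle"]["clinical"]
                if "bundle" in state
                else io.read_metadata(cfg["clinical"])
            )
            design = meta.table.loc[list(dm_w.ids), "group"]
            adonis_rows = []
            for dm, name in ((dm_w, "weighted"), (dm_u, "unweighted")):
                res = community.permanova(
                    dm, design,
                    n_permutations=cfg["adonis"]["n_permutations"],
                    rng_seed=cfg["rng_seed"],
                )
                adonis_rows.append(
                    {"distance": name, "covariate": "group", "R2": res.R2,
                     "pseudo_F": res.pseudo_F, "p_value": res.p_value}
                )
            state.update(dm_w=dm_w, dm_u=dm_u, meta=meta)
            io.write_distance_matrix(dm_w, out / "unifrac_weighted.tsv")
            io.write_distance_matrix(dm_u, out / "unifrac_unweighted.tsv")
            ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                                       float_format="%.12g")
            pd.DataFrame(adonis_rows).to_csv(out / "adonis.tsv", sep="\t", index=False,
                                             float_format="%.12g")
            record(
                "community",
                {n: out / n for n in (
                    "unifrac_weighted.tsv", "unifrac_unweighted.tsv",
                    "pcoa_coordinates.tsv", "adonis.tsv")},
                t0,
            )

        if enabled.get("differential"):
            t0 = time.monotonic()
            meta = state["meta"] if "meta" in state else io.read_metadata(cfg["clinical"])
            groups = meta.table["group"]
            ko_diff = differential.wilcoxon_per_feature(
                state["ko_table"], groups.loc[state["ko_table"].sample_ids],
                alpha=cfg["diff"]["alpha"], adjust=cfg["diff"]["adjust"],
            )
            state["ko_diff"] = ko_diff
            rows = [
                {"feature_id": r.feature_id, "statistic": r.statistic,
                 "p_value": r.p_value, "effect": r.effect, "direction": r.direction,
                 "significant": r.significant}
                for r in ko_diff
            ]
            pd.DataFrame(rows).to_csv(out / "ko_differential.tsv", sep="\t",
                                      index=False, float_format="%.12g")
            record("differential", {"ko_differential.tsv": out / "ko_differential.tsv"}, t0)

        if enabled.get("reporter"):
            t0 = time.monotonic()
            hierarchy = (
                state["bundle"]["pathways"]
                if "bundle" in state
                else io.read_pathways(cfg["pathways"])
            )
            z_map = reporter.ko_signed_z(state["ko_diff"])
            directions = {r.feature_id: r.direction for r in state["ko_diff"]}
            scores = reporter.reporter_scores(
                z_map, hierarchy,
                n_background=cfg["reporter"]["n_background"],
                rng_seed=cfg["rng_seed"], directions=directions,
            )
            sig = reporter.significant_pathways(scores, threshold=cfg["reporter"]["threshold"])
            rows = [
                {"pathway_id": r.pathway_id, "k": r.k, "Z_raw": r.z_raw,
                 "Z_adj": r.z_adj, "direction": r.direction,
                 "significant": abs(r.z_adj) > cfg["reporter"]["threshold"]}
                for r in sorted(scores, key=lambda s: s.pathway_id)
            ]
            pd.DataFrame(rows).to_csv(out / "reporter_scores.tsv", sep="\t",
                                      index=False, float_format="%.12g")
            state["significant_pathways"] = sig
            record("reporter", {"reporter_scores.tsv": out / "reporter_scores.tsv"}, t0)

        if enabled.get("network"):
            t0 = time.monotonic()
            meta = state["meta"] if "meta" in state else io.read_metadata(cfg["clinical"])
            feats = state.get("mgs_profile") or state["bundle"]["genus_table"]
            clin = meta.table[meta.clinical_variables].T
            corr, npairs = networks.spearman_matrix(
                feats.values, clin, min_pairs=cfg["network"]["min_pairs"]
            )
            from .datamodel import CLINICAL_CLASSES

            node_meta = {
                str(f): {"node_class": "MGS",
                         "mean_abundance": float(feats.values.loc[f].mean())}
                for f in feats.values.index
            }
            node_meta.update(
                {v: {"node_class": CLINICAL_CLASSES.get(v, "other")} for v in clin.index}
            )
            net = networks.build_network(
                corr, npairs, threshold=cfg["network"]["threshold"], node_metadata=node_meta
            )
            io.write_network(net, out / "network.graphml", dialect="graphml")
            io.write_network(net, out / "network_edges.tsv", dialect="edgelist")
            state["network"] = net
            record(
                "network",
                {"network.graphml": out / "network.graphml",
                 "network_edges.tsv": out / "network_edges.tsv"},
                t0,
            )

        if enabled.get("qpcr"):
            t0 = time.monotonic()
            if "bundle" in state:
                standards = state["bundle"]["standards"]
                ct = state["bundle"]["longitudinal_ct"]
                long_md = state["bundle"]["longitudinal_metadata"]
            else:
                standards = [
                    tuple(p) for p in
                    pd.read_csv(cfg["standards"]).to_numpy()
                ]
                ct = pd.read_csv(cfg["qpcr_ct"], index_col=0).iloc[:, 0]
                long_md = io.read_metadata(cfg["longitudinal"])
            curve = qpcr.fit_standard_curve(standards)
            results = qpcr.quantify(
                ct, curve,
                grams_assayed=cfg["qpcr"]["grams_assayed"],
                dilution_factor=cfg["qpcr"]["dilution_factor"],
                cfu_per_copy=cfg["qpcr"]["cfu_per_copy"],
            )
            summary = qpcr.colonization_summary(results, long_md)
            summary.to_csv(out / "colonization_summary.tsv", sep="\t", index=False,
                           float_format="%.12g")
            state["colonization"] = summary
            record("qpcr", {"colonization_summary.tsv": out / "colonization_summary.tsv"}, t0)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage and re-raise
        done = set(manifest["stages"])
        failing = next((s for s in STAGES if enabled.get(s) and s not in done), "?")
        raise RuntimeError(f"pipeline stage {failing!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
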