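"""Gene-abundance computation and aggregation to functional/taxonomic profiles.

The two-step normalisation: per sample, the copy number of gene *i* is
``b_i = x_i / L_i`` (mapped reads over gene length), and its relative
abundance is ``a_i = b_i / sum_i b_i``.  Gene profiles roll up to KO, genus
or MGS tables by summing member features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import FeatureTable, GeneCountMatrix, HitTable, ValidationError

__all__ = [
    "compute_copy_numbers",
    "normalize_relative",
    "aggregate_by_map",
    "best_hit_ko_map",
]

UNASSIGNED = "unassigned"


def compute_copy_numbers(gcm: GeneCountMatrix) -> FeatureTable:
    """b_i = x_i / L_i per gene and sample."""
    vals = gcm.counts.to_numpy(dtype=float) / gcm.lengths.to_numpy(dtype=float)[:, None]
    return FeatureTable(
        values=pd.DataFrame(vals, index=gcm.counts.index, columns=gcm.counts.columns),
        kind="copy_number",
    )


def normalize_relative(ft: FeatureTable) -> FeatureTable:
    """a_i = b_i / sum_i b_i per sample column; all-zero columns are an error."""
    arr = ft.values.to_numpy(dtype=float)
    sums = arr.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if len(zero):
        raise ValidationError(
            f"sample {ft.values.columns[zero[0]]!r} has zero total abundance"
        )
    return FeatureTable(
        values=pd.DataFrame(arr / sums, index=ft.values.index, columns=ft.values.columns),
        kind="relative",
    )


def aggregate_by_map(
    ft: FeatureTable,
    feature_map: dict[str, str],
    unmapped_policy: str = "bucket",
) -> FeatureTable:
    """Sum member-feature values into groups given a (possibly partial) map.

    ``unmapped_policy``: ``bucket`` collects unmapped features under an
    ``unassigned`` row (column mass is conserved exactly), ``drop`` discards
    them.
    """
    if not feature_map:
        raise ValidationError("empty feature map")
    if unmapped_policy not in ("drop", "bucket"):
        raise ValidationError(f"unknown unmapped policy {unmapped_policy!r}")
    groups = pd.Index(ft.values.index).map(
        lambda f: feature_map.get(f, UNASSIGNED)
    )
    out = ft.values.groupby(groups.to_numpy()).sum()
    if unmapped_policy == "drop" and UNASSIGNED in out.index:
        out = out.drop(index=UNASSIGNED)
    out = out.sort_index()
    kind = ft.kind if ft.kind != "relative" or unmapped_policy == "bucket" else "count"
    # dropping unmapped mass breaks the column-sum-1 invariant, so demote the tag
    if ft.kind == "relative" and unmapped_policy == "drop":
        kind = "copy_number"
    return FeatureTable(values=out, kind=kind)


def best_hit_ko_map(
    hits: HitTable, e_max: float = 1e-5, bit_min: float = 60.0
) -> dict[str, str]:
    """Map each gene to the KO of its best passing alignment.

    A row passes when e_value <= ``e_max`` and bit_score > ``bit_min``
    (strict).  Among passing rows the gene takes the KO with the highest bit
    score; ties break by lowest e-value, then lexicographic KO id.
    """
    df = hits.rows
    passing = df[(df["e_value"] <= e_max) & (df["bit_score"] > bit_min)]
    if passing.empty:
        return {}
    ranked = passing.sort_values(
        by=["bit_score", "e_value", "subject_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates(subset="gene_id", keep="first")
    return dict(zip(best["gene_id"], best["subject_id"]))
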