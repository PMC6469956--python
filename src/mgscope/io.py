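"""Readers and writers for the tabular and tree formats the pipeline touches.

Canonical table dialect: TSV, UTF-8, header row, ids in the first column,
"." as decimal separator.  Trees are newick (polytomies and unlabeled
internal nodes allowed); networks are written as GraphML and as a 3-column
edge list.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
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

log = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "gene_id", "subject_id", "identity", "aln_len", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "e_value", "bit_score",
]


def read_gene_counts(path_counts, path_lengths) -> GeneCountMatrix:
    """Load a gene x sample count TSV plus a gene-length TSV.

    The counts file has sample ids in the header and gene ids in the first
    column; the lengths file maps gene id -> integer nucleotide length.
    Genes present in counts but absent from lengths are an error.
    """
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    lengths = pd.read_csv(path_lengths, sep="\t", index_col=0).iloc[:, 0]
    counts.index = counts.index.astype(str)
    lengths.index = lengths.index.astype(str)
    return GeneCountMatrix(counts=counts, lengths=lengths)


def read_feature_table(path, kind: str = "count") -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return FeatureTable(values=df, kind=kind)


def write_feature_table(ft: FeatureTable, path) -> None:
    # default float repr is shortest-exact, so read∘write is lossless
    ft.values.to_csv(path, sep="\t")


def read_hit_table(path, gene_lengths: pd.Series) -> HitTable:
    """Read a 12-column BLAST-outfmt6-like TSV and derive per-row coverage.

    Coverage = alignment length over full gene length x 100; gene ids absent
    from ``gene_lengths`` are an error.  An optional 13th column carries a
    semicolon-separated taxonomic lineage for the subject.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == len(BLAST6_COLUMNS) + 1:
        df.columns = BLAST6_COLUMNS + ["taxon_label"]
    elif df.shape[1] == len(BLAST6_COLUMNS):
        df.columns = BLAST6_COLUMNS
        df["taxon_label"] = ""
    else:
        raise ValidationError(
            f"expected 12 or 13 tab-separated columns, got {df.shape[1]} in {path}"
        )
    df["gene_id"] = df["gene_id"].astype(str)
    unknown = set(df["gene_id"]) - set(gene_lengths.index.astype(str))
    if unknown:
        raise ValidationError(f"hit table references unknown gene ids: {sorted(unknown)[:5]}")
    glen = gene_lengths.copy()
    glen.index = glen.index.astype(str)
    df["coverage"] = df["aln_len"].to_numpy(dtype=float) / glen.reindex(
        df["gene_id"]
    ).to_numpy(dtype=float) * 100.0
    return HitTable(rows=df)


def write_hit_table(hits: HitTable, path) -> None:
    cols = [c for c in BLAST6_COLUMNS if c in hits.rows.columns] + ["taxon_label"]
    hits.rows[cols].to_csv(path, sep="\t", header=False, index=False)


def read_metadata(path, group_levels: tuple[str, ...] = ()) -> SampleMetadata:
    """Read a sample metadata CSV (sample_id, subject_id, group, timepoint, clinical...)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(table=df, group_levels=group_levels)


def write_metadata(md: SampleMetadata, path) -> None:
    md.table.to_csv(path, float_format="%.12g")


def read_tree(path) -> TreeNode:
    """Parse a newick tree; polytomies and zero-length branches are allowed."""
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_pathways(path) -> PathwayHierarchy:
    """Read a pathway hierarchy TSV: pathway_id, name, level2_parent, ko_id (one row per membership)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["pathway_id", "name", "level2", "ko_id"])
    if df.empty:
        log.warning("pathway file %s is empty; returning empty hierarchy", path)
        return PathwayHierarchy(pathways={})
    df.columns = ["pathway_id", "name", "level2", "ko_id"]
    out: dict[str, tuple[str, str, frozenset[str]]] = {}
    for pid, grp in df.groupby("pathway_id", sort=False):
        out[pid] = (grp["name"].iloc[0], grp["level2"].iloc[0], frozenset(grp["ko_id"]))
    return PathwayHierarchy(pathways=out)


def write_pathways(hierarchy: PathwayHierarchy, path) -> None:
    rows = []
    for pid, (name, level2, kos) in hierarchy.pathways.items():
        for ko in sorted(kos):
            rows.append((pid, name, level2, ko))
    pd.DataFrame(rows, columns=["pathway_id", "name", "level2", "ko_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_ko_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_ko_map(ko_map: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(ko_map.items()), columns=["gene_id", "ko_id"]
    ).to_csv(path, sep="\t", index=False)


def write_network(net, path, dialect: str = "graphml") -> None:
    """Write a CorrelationNetwork as GraphML or a 3-column edge list.

    ``dialect`` is ``graphml`` or ``edgelist`` (source, target, R).
    """
    if dialect == "graphml":
        g = nx.Graph()
        for node in net.nodes:
            attrs = {"node_class": node.node_class, "isolated": node.isolated}
            if node.mean_abundance is not None:
                attrs["mean_abundance"] = float(node.mean_abundance)
            g.add_node(node.node_id, **attrs)
        for e in net.edges:
            g.add_edge(e.source, e.target, R=float(e.r), n_pairs=int(e.n_pairs))
        nx.write_graphml(g, str(path))
    elif dialect == "edgelist":
        rows = [(e.source, e.target, e.r) for e in net.edges]
        pd.DataFrame(rows, columns=["source", "target", "R"]).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )
    else:
        raise ValidationError(f"unknown network dialect {dialect!r}")


def write_distance_matrix(dm, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
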