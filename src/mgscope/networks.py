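"""Thresholded Spearman correlation networks.

Edges connect feature/variable pairs whose Spearman rank correlation
exceeds the threshold in absolute value (strictly: R > t or R < -t,
default t = 0.4).  Missing clinical values are handled pairwise-complete;
node size metadata carries mean abundance for microbial nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "NetworkNode",
    "NetworkEdge",
    "CorrelationNetwork",
    "spearman_matrix",
    "build_network",
    "subnetwork_by_class",
]

NODE_CLASSES = ("MGS", "metabolic", "SCFA", "gut_brain", "sex_hormone", "other")


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    node_class: str = "other"
    mean_abundance: float | None = None
    isolated: bool = False


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    r: float
    n_pairs: int


@dataclass
class CorrelationNetwork:
    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[NetworkEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {n.node_id for n in self.nodes}
        seen: set[frozenset[str]] = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValidationError(f"self-edge on {e.source!r}")
            if e.source not in ids or e.target not in ids:
                raise ValidationError(f"edge endpoint missing node: {e.source}-{e.target}")
            key = frozenset((e.source, e.target))
            if key in seen:
                raise ValidationError(f"duplicate edge {e.source}-{e.target}")
            seen.add(key)

    @property
    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((e.source, e.target)) for e in self.edges}


def spearman_matrix(
    X: pd.DataFrame,
    Y: pd.DataFrame | None = None,
    min_pairs: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman R between rows of X and rows of Y (or X with itself).

    Columns are samples; X and Y are aligned on shared sample ids.  Missing
    values are dropped pairwise; entries with fewer than ``min_pairs``
    complete pairs, or a zero-variance margin, are NaN.  Returns (R, n_pairs)
    DataFrames.
    """
    symmetric = Y is None
    if Y is None:
        Y = X
    shared = X.columns.intersection(Y.columns)
    if len(shared) == 0:
        raise ValidationError("no shared samples between the two tables")
    Xv = X[shared].to_numpy(dtype=float)
    Yv = Y[shared].to_numpy(dtype=float)
    R = np.full((Xv.shape[0], Yv.shape[0]), np.nan)
    N = np.zeros(R.shape, dtype=int)
    for i in range(Xv.shape[0]):
        j0 = i + 1 if symmetric else 0
        for j in range(j0, Yv.shape[0]):
            ok = ~(np.isnan(Xv[i]) | np.isnan(Yv[j]))
            n = int(ok.sum())
            N[i, j] = n
            if n < min_pairs:
                continue
            a, b = Xv[i, ok], Yv[j, ok]
            if np.all(a == a[0]) or np.all(b == b[0]):
                log.info("zero-variance pair (%s, %s); R left absent", X.index[i], Y.index[j])
                continue
            R[i, j] = stats.spearmanr(a, b).statistic
    if symmetric:
        iu = np.triu_indices_from(R, k=1)
        R[(iu[1], iu[0])] = R[iu]
        N[(iu[1], iu[0])] = N[iu]
    return (
        pd.DataFrame(R, index=X.index, columns=Y.index),
        pd.DataFrame(N, index=X.index, columns=Y.index),
    )


def build_network(
    corr: pd.DataFrame,
    n_pairs: pd.DataFrame,
    threshold: float = 0.4,
    node_metadata: dict[str, dict] | None = None,
) -> CorrelationNetwork:
    """Edges where R > threshold or R < -threshold (strict); isolated nodes kept.

    ``node_metadata`` maps node id -> {"node_class": ..., "mean_abundance": ...}.
    """
    node_metadata = node_metadata or {}
    symmetric = corr.index.equals(corr.columns)
    edges: list[NetworkEdge] = []
    seen: set[frozenset[str]] = set()
    for i, src in enumerate(corr.index):
        for j, dst in enumerate(corr.columns):
            if src == dst:
                continue
            r = corr.iat[i, j]
            if np.isnan(r) or abs(r) <= threshold:
                continue
            key = frozenset((src, dst))
            if symmetric and key in seen:
                continue
            seen.add(key)
            edges.append(NetworkEdge(str(src), str(dst), float(r), int(n_pairs.iat[i, j])))
    connected = {e.source for e in edges} | {e.target for e in edges}
    all_ids = list(dict.fromkeys([str(x) for x in corr.index] + [str(x) for x in corr.columns]))
    nodes = []
    for nid in all_ids:
        meta = node_metadata.get(nid, {})
        nodes.append(
            NetworkNode(
                node_id=nid,
                node_class=meta.get("node_class", "other"),
                mean_abundance=meta.get("mean_abundance"),
                isolated=nid not in connected,
            )
        )
    return CorrelationNetwork(nodes=nodes, edges=edges)


def subnetwork_by_class(net: CorrelationNetwork, classes) -> CorrelationNetwork:
    """Keep nodes in the given classes; dangling edges are dropped."""
    classes = set(classes)
    unknown = classes - set(NODE_CLASSES)
    if unknown:
        raise ValidationError(f"unknown node class(es): {sorted(unknown)}")
    keep = {n.node_id for n in net.nodes if n.node_class in classes}
    edges = [e for e in net.edges if e.source in keep and e.target in keep]
    connected = {e.source for e in edges} | {e.target for e in edges}
    nodes = [
        NetworkNode(n.node_id, n.node_class, n.mean_abundance, n.node_id not in connected)
        for n in net.nodes
        if n.node_id in keep
    ]
    return CorrelationNetwork(nodes=nodes, edges=edges)
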