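"""Beta-diversity distances, principal-coordinate analysis and PERMANOVA.

Distances: Bray-Curtis and Jaccard for tree-free tables, and unweighted /
weighted-normalised UniFrac against a user-supplied newick tree.  Ordination
is classical PCoA (Gower-centred squared distances).  PERMANOVA uses the
McArdle-Anderson trace formulation, so categorical and continuous
single-covariate designs share one code path; p-values are permutation-based
with the add-one convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .datamodel import FeatureTable, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "bray_curtis",
    "jaccard",
    "unifrac",
    "pcoa",
    "permanova",
    "OrdinationResult",
    "PermanovaResult",
]


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates, eigenvalues and variance explained."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    df_model: int
    df_resid: int


def bray_curtis(ft: FeatureTable) -> DistanceMatrix:
    """BC(i,j) = sum|u-v| / sum(u+v); two all-zero samples get distance 0."""
    X = ft.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    n = X.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (X[:, i] + X[:, j]).sum()
            if denom == 0:
                log.warning(
                    "samples %s and %s are both empty; Bray-Curtis set to 0",
                    ft.values.columns[i], ft.values.columns[j],
                )
                continue
            d[i, j] = d[j, i] = np.abs(X[:, i] - X[:, j]).sum() / denom
    return DistanceMatrix(d, ids=[str(c) for c in ft.values.columns])


def jaccard(ft: FeatureTable, presence_threshold: float = 0.0) -> DistanceMatrix:
    """Jaccard distance on presence (value > threshold)."""
    X = ft.values.to_numpy(dtype=float) > presence_threshold
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    n = X.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = (X[:, i] | X[:, j]).sum()
            if union == 0:
                log.warning("two empty samples; Jaccard set to 0")
                continue
            inter = (X[:, i] & X[:, j]).sum()
            d[i, j] = d[j, i] = 1.0 - inter / union
    return DistanceMatrix(d, ids=[str(c) for c in ft.values.columns])


def _branch_tables(ft: FeatureTable, tree: TreeNode):
    """Per-branch lengths and per-sample descendant abundance sums."""
    leaves = {t.name for t in tree.tips()}
    X = ft.values.to_numpy(dtype=float)
    nonzero = set(np.asarray(ft.values.index)[(X > 0).any(axis=1)])
    missing = sorted(nonzero - leaves)
    if missing:
        raise ValidationError(
            f"features with nonzero abundance absent from tree: {missing[:10]}"
        )
    row_of = {f: i for i, f in enumerate(ft.values.index)}
    n_samples = X.shape[1]
    lengths: list[float] = []
    sums: list[np.ndarray] = []
    # postorder accumulation of descendant abundance through every branch
    acc: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = (
                X[row_of[node.name]].copy()
                if node.name in row_of
                else np.zeros(n_samples)
            )
        else:
            vec = np.zeros(n_samples)
            for child in node.children:
                vec += acc[id(child)]
        acc[id(node)] = vec
        if node.parent is not None:  # root carries no branch
            lengths.append(float(node.length or 0.0))
            sums.append(vec)
    return np.asarray(lengths), np.vstack(sums) if sums else np.zeros((0, n_samples))


def unifrac(ft: FeatureTable, tree: TreeNode, mode: str = "unweighted") -> DistanceMatrix:
    """Phylogenetic distance between sample pairs.

    ``unweighted``: fraction of total branch length unique to one community.
    ``weighted_normalized``: sum_b l_b |pA - pB| / sum_b l_b (pA + pB) with
    p the fraction of a sample's total abundance descending through branch b.
    Both modes are bounded in [0, 1].
    """
    if mode not in ("unweighted", "weighted_normalized"):
        raise ValidationError(f"unknown UniFrac mode {mode!r}")
    lengths, sums = _branch_tables(ft, tree)
    totals = ft.values.to_numpy(dtype=float).sum(axis=0)
    n = len(totals)
    empty = np.where(totals == 0)[0]
    if len(empty):
        raise ValidationError(
            f"sample {ft.values.columns[empty[0]]!r} has zero total abundance under the tree"
        )
    P = sums / totals  # branch x sample proportions
    present = sums > 0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "unweighted":
                either = present[:, i] | present[:, j]
                one = present[:, i] ^ present[:, j]
                denom = lengths[either].sum()
                d[i, j] = d[j, i] = lengths[one].sum() / denom if denom > 0 else 0.0
            else:
                num = (lengths * np.abs(P[:, i] - P[:, j])).sum()
                denom = (lengths * (P[:, i] + P[:, j])).sum()
                d[i, j] = d[j, i] = num / denom if denom > 0 else 0.0
    return DistanceMatrix(d, ids=[str(c) for c in ft.values.columns])


def _gower_center(dm: DistanceMatrix) -> np.ndarray:
    D2 = np.asarray(dm.data, dtype=float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); only positive
    eigenvalues are embedded, negative ones are reported as diagnostics.
    """
    G = _gower_center(dm)
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(abs(eigvals).max(), 1.0)
    pos = eigvals > tol
    neg = eigvals[eigvals < -tol]
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            log.warning(
                "requested %d axes but only %d positive eigenvalues; truncating",
                n_axes, coords.shape[1],
            )
        coords = coords[:, :n_axes]
        lam_kept = lam[: coords.shape[1]]
    else:
        lam_kept = lam
    prop = lam_kept / lam.sum() if lam.size else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=list(dm.ids),
            columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
        ),
        eigenvalues=lam_kept,
        proportion_explained=prop,
        negative_eigenvalues=neg,
    )


def _model_matrix(design: pd.Series) -> np.ndarray:
    """Column-centred model matrix: dummy codes for categorical, as-is for real."""
    vals = design.to_numpy()
    if vals.dtype.kind in "fiu" and len(np.unique(vals)) > 2:
        X = vals.astype(float)[:, None]
    else:
        levels = pd.unique(vals)
        if len(levels) < 2:
            raise ValidationError("design has fewer than 2 distinct values")
        X = np.column_stack([(vals == lv).astype(float) for lv in levels[1:]])
    return X - X.mean(axis=0)


def permanova(
    dm: DistanceMatrix,
    design,
    n_permutations: int = 999,
    rng_seed: int = 0,
) -> PermanovaResult:
    """Distance-based PERMANOVA (Adonis) for one covariate.

    Trace form: with Gower-centred G and hat matrix H of the centred design,
    SS_model = tr(HGH), SS_total = tr(G); pseudo-F uses model and residual
    degrees of freedom; the p-value permutes sample labels with the add-one
    convention p = (1 + #{F_perm >= F}) / (1 + n_permutations).
    """
    design = pd.Series(design)
    if len(design) != len(dm.ids):
        raise ValidationError("design length does not match distance matrix")
    G = _gower_center(dm)
    X = _model_matrix(design)
    n = G.shape[0]
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
        raise ValidationError("collinear (singular) design")
    H = X @ np.linalg.solve(XtX, X.T)
    df_model = X.shape[1]
    df_resid = n - df_model - 1
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")

    ss_total = float(np.trace(G))
    if ss_total <= 1e-12:
        log.warning("distance matrix has no variation; PERMANOVA is degenerate")
        return PermanovaResult(
            pseudo_F=0.0, R2=0.0, p_value=1.0,
            n_permutations=n_permutations, df_model=df_model, df_resid=df_resid,
        )

    def _stats(perm: np.ndarray) -> tuple[float, float]:
        Gp = G[np.ix_(perm, perm)]
        ss_model = float(np.trace(H @ Gp @ H))
        ss_resid = ss_total - ss_model
        if ss_resid <= 0:
            return np.inf if ss_model > 0 else 0.0, ss_model / ss_total
        f = (ss_model / df_model) / (ss_resid / df_resid)
        return f, ss_model / ss_total

    ident = np.arange(n)
    f_obs, r2 = _stats(ident)
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _ = _stats(rng.permutation(n))
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs, R2=r2, p_value=p,
        n_permutations=n_permutations, df_model=df_model, df_resid=df_resid,
    )
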