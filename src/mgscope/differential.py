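"""Per-feature nonparametric differential-abundance testing.

Two-group comparisons use the Wilcoxon rank-sum test (exact enumeration for
small tie-free groups, tie-corrected normal approximation otherwise),
multi-timepoint comparisons use Kruskal-Wallis, and subject-matched
two-timepoint comparisons default to the Wilcoxon signed-rank test on
within-subject differences.  The study convention is significance at raw
p < 0.01; Benjamini-Hochberg adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import FeatureTable, ValidationError

__all__ = [
    "DifferentialResult",
    "wilcoxon_per_feature",
    "kruskal_per_feature",
    "paired_two_timepoint",
    "bh_adjust",
]


@dataclass
class DifferentialResult:
    feature_id: str
    statistic: float
    p_value: float
    effect: float  # difference of group medians, same units as input
    direction: str  # group label the feature is enriched in ("" for ties)
    significant: bool
    adjusted_p: float | None = None


def _exact_applicable(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(a) <= 8 and len(b) <= 8 and len(np.unique(pooled)) == len(pooled)


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value and U statistic.

    Exact null enumeration when both groups have <= 8 samples and no ties;
    tie-corrected normal approximation with continuity correction otherwise
    (the correction keeps the two branches within ~0.01 of each other at the
    branch boundary).
    """
    method = "exact" if _exact_applicable(a, b) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _result(
    fid: str, stat: float, p: float, a: np.ndarray, b: np.ndarray,
    labels: tuple[str, str], alpha: float,
) -> DifferentialResult:
    effect = float(np.median(a) - np.median(b))
    direction = labels[0] if effect > 0 else labels[1] if effect < 0 else ""
    return DifferentialResult(
        feature_id=fid, statistic=stat, p_value=p, effect=effect,
        direction=direction, significant=p < alpha,
    )


def _group_arrays(ft: FeatureTable, groups: pd.Series):
    groups = pd.Series(groups)
    if not groups.index.equals(pd.Index(ft.values.columns)):
        groups = groups.reindex(ft.values.columns)
    if groups.isna().any():
        raise ValidationError("group labels missing for some samples")
    return groups


def wilcoxon_per_feature(
    ft: FeatureTable,
    groups,
    alpha: float = 0.01,
    adjust: str = "none",
) -> list[DifferentialResult]:
    """Two-sided rank-sum test per feature between two groups.

    Significance is flagged at raw p < ``alpha`` when ``adjust`` is
    ``none``, on the BH-adjusted p otherwise.
    """
    groups = _group_arrays(ft, groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {list(levels)}")
    mask_a = (groups == levels[0]).to_numpy()
    mask_b = (groups == levels[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError("each group needs at least 2 samples")
    X = ft.values.to_numpy(dtype=float)
    out = []
    for i, fid in enumerate(ft.values.index):
        a, b = X[i, mask_a], X[i, mask_b]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = float(len(a) * len(b) / 2), 1.0
        else:
            stat, p = rank_sum_test(a, b)
        out.append(_result(str(fid), stat, p, a, b, (levels[0], levels[1]), alpha))
    if adjust == "bh":
        adj = bh_adjust([r.p_value for r in out])
        for r, q in zip(out, adj):
            r.adjusted_p = float(q)
            r.significant = q < alpha
    elif adjust != "none":
        raise ValidationError(f"unknown adjust {adjust!r}")
    return out


def kruskal_per_feature(
    ft: FeatureTable, groups, alpha: float = 0.05
) -> list[DifferentialResult]:
    """Tie-corrected Kruskal-Wallis H per feature across >= 2 group levels."""
    groups = _group_arrays(ft, groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValidationError("need at least 2 group levels")
    masks = [(groups == lv).to_numpy() for lv in levels]
    if any(m.sum() < 2 for m in masks):
        raise ValidationError("each group needs at least 2 samples")
    X = ft.values.to_numpy(dtype=float)
    out = []
    for i, fid in enumerate(ft.values.index):
        samples = [X[i, m] for m in masks]
        if len(np.unique(X[i])) == 1:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        medians = [float(np.median(s)) for s in samples]
        top = int(np.argmax(medians))
        out.append(
            DifferentialResult(
                feature_id=str(fid), statistic=float(h), p_value=float(p),
                effect=float(max(medians) - min(medians)),
                direction=str(levels[top]) if len(set(medians)) > 1 else "",
                significant=p < alpha,
            )
        )
    return out


def paired_two_timepoint(
    ft: FeatureTable,
    pairs: list[tuple[str, str]],
    method: str = "signed_rank",
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Subject-matched two-timepoint test per feature.

    ``pairs`` lists (sample_at_t1, sample_at_t2) per subject.  The default
    tests within-subject differences with the Wilcoxon signed-rank test
    (exact for n <= 25 without ties); ``method='rank_sum'`` instead applies
    the unpaired rank-sum test to the two timepoint groups.
    """
    for s1, s2 in pairs:
        if s1 not in ft.values.columns or s2 not in ft.values.columns:
            raise ValidationError(f"pair ({s1!r}, {s2!r}) has a missing sample")
    if method == "rank_sum":
        cols = [s for p in pairs for s in p]
        sub = FeatureTable(values=ft.values[cols], kind=ft.kind)
        labels = pd.Series(
            ["t1", "t2"] * len(pairs), index=cols
        )
        # duplicated sample use is fine here: the literal unpaired reading
        return wilcoxon_per_feature(sub, labels, alpha=alpha)
    if method != "signed_rank":
        raise ValidationError(f"unknown method {method!r}")
    X1 = ft.values[[p[0] for p in pairs]].to_numpy(dtype=float)
    X2 = ft.values[[p[1] for p in pairs]].to_numpy(dtype=float)
    out = []
    for i, fid in enumerate(ft.values.index):
        diff = X2[i] - X1[i]
        if np.all(diff == 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(diff, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        effect = float(np.median(diff))
        out.append(
            DifferentialResult(
                feature_id=str(fid), statistic=stat, p_value=p, effect=effect,
                direction="t2" if effect > 0 else "t1" if effect < 0 else "",
                significant=p < alpha,
            )
        )
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
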