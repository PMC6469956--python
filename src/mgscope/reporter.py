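"""Reporter Z-score pathway enrichment.

Each KO receives a signed z from its two-group differential test,
z = Phi^{-1}(1 - p/2) * sign(effect).  A pathway with k scored member KOs
gets Z_raw = sum(z) / sqrt(k), which is corrected against a size-matched
random background: mu_k and sigma_k are estimated from ``n_background``
random size-k KO sets drawn from all scored KOs, and
Z_adj = (Z_raw - mu_k) / sigma_k.  Pathways with |Z_adj| above the
detection threshold (default 2.3) are called significantly shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import PathwayHierarchy
from .differential import DifferentialResult

log = logging.getLogger(__name__)

__all__ = ["ReporterResult", "ko_signed_z", "reporter_scores", "significant_pathways"]

P_CLIP = 1e-15  # caps |z| at ~7.94, avoiding infinities from p == 0


@dataclass
class ReporterResult:
    pathway_id: str
    k: int
    z_raw: float
    mu_k: float
    sigma_k: float
    z_adj: float
    direction: str  # group label the pathway is enriched in, or "mixed"
    member_z: dict[str, float] = field(default_factory=dict)
    degenerate_background: bool = False


def ko_signed_z(diff: list[DifferentialResult]) -> dict[str, float]:
    """Signed z per KO from two-sided p-values: Phi^{-1}(1 - p/2) * sign(effect)."""
    out: dict[str, float] = {}
    for r in diff:
        p = min(max(r.p_value, P_CLIP), 1 - P_CLIP)
        z = float(stats.norm.ppf(1 - p / 2))
        out[r.feature_id] = z * (1 if r.effect > 0 else -1 if r.effect < 0 else 0)
    return out


def reporter_scores(
    z_map: dict[str, float],
    hierarchy: PathwayHierarchy,
    n_background: int = 1000,
    rng_seed: int = 0,
    directions: dict[str, str] | None = None,
) -> list[ReporterResult]:
    """Background-corrected reporter Z per pathway.

    The background for each distinct member count k is ``n_background``
    random size-k subsets (without replacement within a set) of all scored
    KOs, seeded for bit-reproducibility.  Pathways with no scored members
    are skipped; a degenerate background (sigma_k = 0) yields Z_adj = 0 with
    a flag.  ``directions`` optionally maps KO -> enriched-group label used
    to call the pathway direction (majority among members with |z| > 0;
    ties -> "mixed").
    """
    kos = np.array(sorted(z_map))
    zs = np.array([z_map[k] for k in kos])
    rng = np.random.default_rng(rng_seed)

    sizes = sorted(
        {
            len(set(hierarchy.members(pid)) & set(kos))
            for pid in hierarchy
        }
        - {0}
    )
    background: dict[int, tuple[float, float]] = {}
    for k in sizes:
        if k > len(kos):
            continue
        draws = np.empty(n_background)
        for b in range(n_background):
            idx = rng.choice(len(kos), size=k, replace=False)
            draws[b] = zs[idx].sum() / np.sqrt(k)
        background[k] = (float(draws.mean()), float(draws.std(ddof=0)))

    results: list[ReporterResult] = []
    for pid in hierarchy:
        members = sorted(set(hierarchy.members(pid)) & set(kos))
        k = len(members)
        if k == 0:
            continue
        if k not in background:
            log.warning("pathway %s has more members than scored KOs; skipped", pid)
            continue
        member_z = {m: z_map[m] for m in members}
        z_raw = float(sum(member_z.values()) / np.sqrt(k))
        mu_k, sigma_k = background[k]
        # relative epsilon: a background of identical draws has sigma at
        # float-noise scale, which must not amplify rounding differences
        degenerate = sigma_k <= 1e-9 * max(1.0, abs(mu_k))
        z_adj = 0.0 if degenerate else (z_raw - mu_k) / sigma_k
        direction = _call_direction(member_z, directions)
        results.append(
            ReporterResult(
                pathway_id=pid, k=k, z_raw=z_raw, mu_k=mu_k, sigma_k=sigma_k,
                z_adj=float(z_adj), direction=direction, member_z=member_z,
                degenerate_background=degenerate,
            )
        )
    return results


def _call_direction(member_z: dict[str, float], directions: dict[str, str] | None) -> str:
    if directions:
        votes: dict[str, int] = {}
        for ko, z in member_z.items():
            if z != 0 and directions.get(ko):
                lab = directions[ko]
                votes[lab] = votes.get(lab, 0) + 1
        if not votes:
            return "mixed"
        top = max(votes.values())
        winners = [lab for lab, v in votes.items() if v == top]
        return winners[0] if len(winners) == 1 else "mixed"
    up = sum(1 for z in member_z.values() if z > 0)
    down = sum(1 for z in member_z.values() if z < 0)
    return "up" if up > down else "down" if down > up else "mixed"


def significant_pathways(
    results: list[ReporterResult], threshold: float = 2.3
) -> list[ReporterResult]:
    """Keep pathways with |Z_adj| strictly above ``threshold``, sorted by |Z_adj| desc."""
    kept = [r for r in results if abs(r.z_adj) > threshold]
    return sorted(kept, key=lambda r: (-abs(r.z_adj), r.pathway_id))
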