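"""Strain-specific qPCR quantification.

A log-linear standard curve (Ct = slope * log10(copies) + intercept, slope
< 0) converts cycle thresholds to copies per reaction and on to log10 CFU
per gram of feces.  Amplification efficiency derives from the slope as
(10^(-1/slope) - 1) * 100, so a perfect doubling per cycle (slope
-1/log10(2) = -3.3219) is 100%.  Colonization summaries aggregate log
CFU/g by group and timepoint over the consumption/washout schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import SampleMetadata, ValidationError

__all__ = [
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "quantify",
    "colonization_summary",
    "PHASE_OF_TIMEPOINT",
]

#: study schedule: A = baseline, B/D/F sampled during consumption, C/E/G after washout
PHASE_OF_TIMEPOINT = {
    "A": "baseline",
    "B": "consumption", "D": "consumption", "F": "consumption",
    "C": "washout", "E": "washout", "G": "washout",
}


@dataclass
class StandardCurve:
    slope: float  # Ct per log10(copies); negative
    intercept: float  # Ct at 1 copy
    r_squared: float
    efficiency: float  # percent

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError(f"standard curve slope must be negative, got {self.slope}")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError(f"r_squared out of [0,1]: {self.r_squared}")

    def ct_of(self, log10_copies: float) -> float:
        return self.slope * log10_copies + self.intercept


@dataclass
class QuantResult:
    sample_id: str
    ct: float
    copies_per_reaction: float
    log_cfu_per_gram: float
    extrapolated: bool = False


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """OLS fit of Ct on log10(copies) over >= 3 distinct concentrations."""
    if len(points) < 3:
        raise ValidationError("need at least 3 standard points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValidationError("need at least 3 distinct concentrations")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValidationError(f"invalid standard curve: non-negative slope {fit.slope}")
    efficiency = (10 ** (-1 / fit.slope) - 1) * 100
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(efficiency),
    )


def quantify(
    ct_values: pd.Series,
    curve: StandardCurve,
    grams_assayed: float = 1.0,
    dilution_factor: float = 1.0,
    cfu_per_copy: float = 1.0,
    ct_range: tuple[float, float] | None = None,
) -> list[QuantResult]:
    """Invert the standard curve: copies = 10^((Ct - intercept)/slope).

    log CFU/g = log10(copies * dilution_factor / grams_assayed * cfu_per_copy).
    ``ct_range`` (min, max observed on the standards) flags extrapolated Cts.
    """
    if grams_assayed <= 0:
        raise ValidationError("grams_assayed must be positive")
    out = []
    for sid, ct in ct_values.items():
        copies = 10 ** ((float(ct) - curve.intercept) / curve.slope)
        cfu_per_gram = copies * dilution_factor / grams_assayed * cfu_per_copy
        extrap = bool(ct_range and not (ct_range[0] <= ct <= ct_range[1]))
        out.append(
            QuantResult(
                sample_id=str(sid), ct=float(ct),
                copies_per_reaction=float(copies),
                log_cfu_per_gram=float(np.log10(cfu_per_gram)),
                extrapolated=extrap,
            )
        )
    return out


def colonization_summary(results: list[QuantResult], metadata: SampleMetadata) -> pd.DataFrame:
    """Mean +/- sd of log CFU/g per (group, timepoint), with phase labels.

    Rows cover every group x timepoint cell present in the metadata; empty
    cells report n = 0.
    """
    vals = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "log_cfu_per_gram": [r.log_cfu_per_gram for r in results],
        }
    ).set_index("sample_id")
    joined = metadata.table.join(vals, how="left")
    rows = []
    for (group, tp), cell in joined.groupby(["group", "timepoint"], sort=True):
        x = cell["log_cfu_per_gram"].dropna()
        rows.append(
            {
                "group": group,
                "timepoint": tp,
                "phase": PHASE_OF_TIMEPOINT.get(str(tp), "unknown"),
                "n": int(len(x)),
                "mean_log_cfu_per_gram": float(x.mean()) if len(x) else np.nan,
                "sd_log_cfu_per_gram": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
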