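"""Strain-specific qPCR quantification of the probiotic across the
longitudinal arm: standard curve, Ct inversion, and colonization summaries
for responders vs non-responders; Kruskal-Wallis on the clinical
trajectories."""

import pandas as pd

from common import RESULTS, study_bundle
from mgscope.datamodel import FeatureTable
from mgscope.differential import kruskal_per_feature
from mgscope.qpcr import colonization_summary, fit_standard_curve, quantify

bundle = study_bundle()
curve = fit_standard_curve(bundle["standards"])
print(f"standard curve: slope {curve.slope:.4f} Ct/log10(copies), "
      f"intercept {curve.intercept:.2f}, r^2 {curve.r_squared:.4f}, "
      f"efficiency {curve.efficiency:.1f}%")

results = quantify(bundle["longitudinal_ct"], curve)
summary = colonization_summary(results, bundle["longitudinal_metadata"])
summary.to_csv(RESULTS / "colonization_summary.tsv", sep="\t", index=False,
               float_format="%.4g")

for group in ("R", "N"):
    cell = summary[(summary.group == group) & (summary.phase == "consumption")]
    mean = (cell["mean_log_cfu_per_gram"] * cell["n"]).sum() / cell["n"].sum()
    sd = cell["sd_log_cfu_per_gram"].mean()
    print(f"group {group} consumption phase: {mean:.2f} +/- {sd:.2f} "
          f"log CFU/g (n={int(cell['n'].sum())})")

# clinical trajectories across the four consumption-stage weeks, per group
md = bundle["longitudinal_metadata"].table
week_points = md[md.timepoint.isin(["A", "B", "D", "F"])]
for group in ("R", "N"):
    sub = week_points[week_points.group == group]
    ft = FeatureTable(
        values=pd.DataFrame({"LH": sub["LH"], "acetic_acid": sub["acetic_acid"]})
        .T.set_axis(sub.index, axis=1)
    )
    res = kruskal_per_feature(ft, sub["timepoint"], alpha=0.05)
    for r in res:
        print(f"group {group} {r.feature_id}: Kruskal-Wallis H={r.statistic:.2f}, "
              f"p={r.p_value:.2e}{' *' if r.significant else ''}")
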