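"""Beta diversity of the genus-level community: weighted/unweighted UniFrac,
PCoA, and per-covariate Adonis (PERMANOVA) for the disease factor and the
clinical variables."""

import pandas as pd

from common import RESULTS, SEED, study_bundle
from mgscope import io
from mgscope.community import pcoa, permanova, unifrac

bundle = study_bundle()
genus = bundle["genus_table"]
tree = bundle["tree"]
meta = bundle["clinical"]

dm_w = unifrac(genus, tree, mode="weighted_normalized")
dm_u = unifrac(genus, tree, mode="unweighted")
io.write_distance_matrix(dm_w, RESULTS / "unifrac_weighted.tsv")
io.write_distance_matrix(dm_u, RESULTS / "unifrac_unweighted.tsv")

ordn = pcoa(dm_w, n_axes=2)
ordn.coordinates.to_csv(RESULTS / "pcoa_weighted.tsv", sep="\t")
print("PCoA (weighted UniFrac): "
      f"PC1 {ordn.proportion_explained[0]:.1%}, "
      f"PC2 {ordn.proportion_explained[1]:.1%} of variance")

rows = []
covariates = ["group", "LH", "T", "TG", "PYY", "acetic_acid", "FPG", "E2"]
for cov in covariates:
    design = meta.table.loc[list(dm_w.ids), cov]
    res = permanova(dm_w, design, n_permutations=999, rng_seed=SEED)
    rows.append({"covariate": cov, "R2": res.R2, "pseudo_F": res.pseudo_F,
                 "p_value": res.p_value})
adonis = pd.DataFrame(rows)
adonis.to_csv(RESULTS / "adonis_weighted.tsv", sep="\t", index=False,
              float_format="%.6g")
print("\nAdonis on weighted UniFrac (999 permutations):")
print(adonis.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
disease_r2 = adonis.loc[adonis.covariate == "group", "R2"].iloc[0]
uncoupled = adonis[adonis.covariate.isin(["TG", "FPG", "E2"])]["R2"]
print(f"\ndisease-factor R2 {disease_r2:.3f} vs max R2 {uncoupled.max():.3f} "
      "among variables with no planted community coupling (TG, FPG, E2): "
      "the group effect dominates; LH/T/PYY/acetic acid track it through "
      "their planted species couplings")
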