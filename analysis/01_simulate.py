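"""Generate the synthetic two-group cohort and write every pipeline input.

The cohort mirrors the study design: 20 control + 20 case samples with deep
shotgun gene counts from 10 planted species, a KO/pathway layer with two
planted differential pathways, Table-1-style clinical variables coupled to
species abundances, and a 14-subject longitudinal probiotic arm (9
responders / 5 non-responders) with qPCR readouts.
"""

import pandas as pd

from common import RESULTS, SEED, study_bundle
from mgscope import io
from mgscope.abundance import compute_copy_numbers

bundle = study_bundle()
out = io.ensure_dir(RESULTS / "inputs")

gcm = bundle["gene_counts"]
gcm.counts.to_csv(out / "gene_counts.tsv", sep="\t")
gcm.lengths.to_frame("length").to_csv(out / "gene_lengths.tsv", sep="\t")
io.write_ko_map(bundle["ko_map"], out / "gene_ko_map.tsv")
io.write_pathways(bundle["pathways"], out / "pathways.tsv")
io.write_metadata(bundle["clinical"], out / "clinical.csv")
io.write_hit_table(bundle["hits"], out / "hits.tsv")
io.write_tree(bundle["tree"], out / "species_tree.nwk")
io.write_feature_table(bundle["genus_table"], out / "genus_table.tsv")
bundle["longitudinal_ct"].to_frame().to_csv(out / "qpcr_ct.csv")
io.write_metadata(bundle["longitudinal_metadata"], out / "longitudinal.csv")
pd.Series(bundle["truth"]["gene_species"]).to_frame("species").to_csv(
    out / "truth_gene_species.tsv", sep="\t"
)

n_genes, n_samples = gcm.counts.shape
depth = gcm.counts.sum(axis=0)
print(f"seed {SEED}: {n_genes} genes x {n_samples} samples "
      f"({(bundle['truth']['group'] == 'control').sum()} control / "
      f"{(bundle['truth']['group'] == 'case').sum()} case)")
print(f"mean depth {depth.mean():,.0f} reads/sample "
      f"(range {depth.min():,.0f}-{depth.max():,.0f})")
print(f"KO map covers {len(bundle['ko_map'])} genes -> "
      f"{len(set(bundle['ko_map'].values()))} KOs; "
      f"{len(bundle['pathways'])} pathways "
      f"({len(bundle['truth']['planted_pathways'])} planted differential)")
print(f"inputs written under {out}")
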