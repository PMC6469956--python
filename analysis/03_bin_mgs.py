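"""Bin genes into co-abundance gene groups (CAGs), flag MGS (>50 genes),
assign rule-based taxonomy, and score recovery of the planted species."""

import pandas as pd

from common import RESULTS, study_bundle
from mgscope import io
from mgscope.abundance import compute_copy_numbers
from mgscope.mgs import assign_taxonomy, canopy_cluster, filter_mgs, mgs_abundance
from mgscope.validation import adjusted_rand_index

bundle = study_bundle()
copy = compute_copy_numbers(bundle["gene_counts"])
cags = canopy_cluster(copy)
catalog = assign_taxonomy(filter_mgs(cags, min_mgs_size=50), bundle["hits"])
profile = mgs_abundance(catalog, copy)

truth = bundle["truth"]["gene_species"]
assign = {g: c.cag_id for c in cags for g in c.member_gene_ids}
genes = sorted(truth)
ari = adjusted_rand_index(
    [truth[g] for g in genes], [assign.get(g, "none") for g in genes]
)

membership = pd.DataFrame(
    [(g, c.cag_id) for c in cags for g in sorted(c.member_gene_ids)],
    columns=["gene_id", "cag_id"],
)
membership.to_csv(RESULTS / "cag_membership.tsv", sep="\t", index=False)
tax = pd.DataFrame.from_dict(catalog.taxonomy, orient="index")
tax.index.name = "cag_id"
tax.to_csv(RESULTS / "mgs_taxonomy.tsv", sep="\t")
io.write_feature_table(profile, RESULTS / "mgs_profile.tsv")

print(f"{len(cags)} CAGs; {len(catalog.mgs)} pass the >50-gene MGS rule")
print(f"adjusted Rand index vs planted species partition: {ari:.4f}")
assigned = sum(1 for t in catalog.taxonomy.values() if t["assigned_genome"])
print(f"taxonomy: {assigned}/{len(catalog.mgs)} MGS assigned a genome "
      f"(80% vote at 95% identity / 90% coverage)")
for cag_id, t in catalog.taxonomy.items():
    print(f"  {cag_id}: genome={t['assigned_genome']}, "
          f"taxon={t['assigned_taxon']} ({t['rank']})")
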