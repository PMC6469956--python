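# mgscope

A tested, reusable implementation of the computational pipeline behind a
two-phase gut-microbiome study of polycystic ovary syndrome (PCOS) and a
probiotic (*Bifidobacterium lactis*) intervention: from shotgun gene counts
to species-level bins, pathway shifts, community-level statistics,
microbe–clinical correlation networks, and strain-specific qPCR
colonization estimates.  It is aimed at microbiome researchers who want the
analysis chain of such studies as importable, seedable, property-tested
Python rather than a collection of one-off scripts.

## What it computes

- **Gene abundance** — for sample *N*, copy number *b\_i = x\_i / L\_i*
  (mapped reads over gene length) and relative abundance
  *a\_i = b\_i / Σ\_i b\_i*; roll-ups to KO, genus or MGS profiles.
- **CAG / MGS binning** — deterministic canopy clustering of gene
  copy-number profiles by Pearson correlation (collect at *r* ≥ 0.9 to a
  seed profile, per-sample-median canopy profiles, merge at *r* ≥ 0.97,
  shadow-canopy removal).  Co-abundance gene groups with more than 50
  member genes are metagenomic species (MGS).  Taxonomy is assigned by
  vote: a gene matches a genome at ≥ 95% identity over ≥ 90% of the gene
  length, and an MGS takes a genome/taxon when more than 80% of its genes
  agree.
- **Reporter Z-scores** — per-KO signed *z* = Φ⁻¹(1 − p/2)·sign(effect)
  from two-sided Wilcoxon tests; pathway score *Z\_raw = Σz / √k*
  corrected against a size-matched random-KO background,
  *Z\_adj = (Z\_raw − μ\_k)/σ\_k*; pathways with |*Z\_adj*| > 2.3 are
  called shifted.
- **Community statistics** — unweighted and weighted-normalised UniFrac
  against a newick tree (plus Bray–Curtis/Jaccard), classical PCoA, and
  single-covariate PERMANOVA (Adonis) in the McArdle–Anderson trace form
  with permutation p-values.
- **Differential abundance** — per-feature Wilcoxon rank-sum (exact for
  small tie-free groups), Kruskal–Wallis across timepoints, paired
  signed-rank tests, Benjamini–Hochberg adjustment; significance at raw
  *P* < 0.01 by default.
- **Correlation networks** — pairwise Spearman *R* with pairwise-complete
  missing handling; edges strictly at *R* > 0.4 or *R* < −0.4; node
  classes (MGS, metabolic, SCFA, gut–brain, sex hormone) and
  mean-abundance node metadata; GraphML and edge-list output.
- **qPCR quantification** — log-linear standard curve (Ct on log₁₀ copies),
  amplification efficiency (10^(−1/slope) − 1)·100, Ct → copies → log CFU
  per gram of feces, and colonization summaries by group × timepoint over
  a baseline / consumption / washout schedule.
- **Synthetic cohort generator** — a seeded stand-in for the study data:
  planted species with known gene membership, planted differential
  pathways, clinical variables monotonically coupled to species
  abundances, and a longitudinal responder/non-responder arm colonized at
  6.93 ± 0.42 log CFU/g.  Every dataset ships with its ground truth so
  each stage can be scored for recovery.

## Worked example

The numbered drivers under `analysis/` run the full chain on the default
synthetic cohort (20 control + 20 case samples, 10 species, seed 1) and
write tables under `results/analysis/`:

```
cd analysis
python 01_simulate.py
python 03_bin_mgs.py
python 06_pathway_enrichment.py
```

prints, among other things:

```
10 CAGs; 6 pass the >50-gene MGS rule
adjusted Rand index vs planted species partition: 1.0000
taxonomy: 6/6 MGS assigned a genome (80% vote at 95% identity / 90% coverage)
...
4/20 pathways with |Z_adj| > 2.3
planted pathways ['path001', 'path002'] rank [1, 2] of 20 by |Z_adj|
```

i.e. canopy clustering recovers the planted species partition exactly
(adjusted Rand index 1.0), the >50-gene rule keeps 6 species-level bins,
every one is assigned its true genome by the 80%/95%/90% vote, and the two
pathways planted with a four-fold between-group shift are the two
strongest reporter signals.  `04_community_structure.py` prints the Adonis
table (disease-factor R² ≈ 0.11, *p* = 0.001 on weighted UniFrac);
`08_qpcr_colonization.py` fits the standard curve (efficiency ≈ 100%) and
reports responders at ≈ 6.8 log CFU/g during consumption versus ≈ 2.2 in
non-responders.

The same chain is scriptable from one config:

```python
from mgscope.pipeline import run_pipeline, default_config
manifest = run_pipeline(default_config("out_dir", seed=1))
```

which executes simulate → abundance → bin-mgs → community → differential →
reporter → network → qpcr and writes a checksum manifest; reruns with the
same seed are byte-identical.

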