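# Methods

This note documents the models and procedures mgscope implements, the
parameters that matter, the synthetic study conditions used for testing,
and the numerical and design choices made where the underlying methods
left them open.

## Gene abundance

For each sample, gene copy number is the mapped-read count divided by gene
length, `b_i = x_i / L_i`, and relative abundance renormalises per sample,
`a_i = b_i / Σ_i b_i`.  Genes absent from a sample keep an explicit zero
(dense semantics).  Roll-ups (`aggregate_by_map`) sum member features per
group; with the default `bucket` policy unannotated features collect under
`unassigned`, so relative columns still sum to one exactly; the `drop`
policy discards them and the result is re-tagged as unnormalised.  KO
assignment takes, per gene, the best alignment with e-value ≤ 1e−5 and bit
score strictly greater than 60, preferring higher bit score, then lower
e-value, then lexicographic KO id — the two tie-breaks make the map
deterministic where "highest score" alone is ambiguous.

## CAG binning and MGS calling

Canopy clustering on Pearson correlation of *untransformed copy-number*
profiles (relative abundances are avoided because closure induces spurious
negative correlation between large features):

1. Genes observed (> 0) in fewer than `min_obs = 3` samples are set aside.
2. Seeds are visited in descending total copy number (ties lexicographic).
   An unassigned seed collects all unassigned genes with r ≥ `tight_r`
   (default 0.9) to its profile; the canopy profile is the per-sample
   median of members and membership is re-collected to a fixed point
   (≤ 10 rounds).  The seed anchors its canopy and cannot drop out.
3. Canopies whose median profiles correlate ≥ `merge_r` (default 0.97)
   merge greedily, most-correlated pair first.
4. "Shadow" canopies in which one sample carries more than
   `shadow_frac = 0.9` of the profile's total signal are discarded —
   single-sample spikes produce chimeric bins.

The thresholds are not dictated by the co-abundance principle itself; the
defaults are the operating point of the published canopy-based gene-binning
literature this family of methods derives from, and all four are exposed.
Output is a partition: every clustered gene belongs to exactly one CAG,
and the result is invariant to input gene order (the seed order is
canonical, not positional).

A CAG with **more than 50** member genes (strict) is an MGS.  Taxonomy per
MGS: a gene *matches* genome G when it has at least one hit at ≥ 95%
identity and ≥ 90% coverage of the gene length; G is assigned when more
than 80% of member genes match it (unique because 0.8 ≥ 0.5).
Independently, ranks are walked species → phylum using each gene's
best-passing-hit lineage, assigning the first rank where one label exceeds
the 80% vote.  Hits covering genes outside any MGS are counted and
ignored.  MGS per-sample signal is the **median** of member-gene copy
numbers (robust to a few mis-binned or multi-copy genes), renormalised to
a relative MGS profile.

## Community statistics

UniFrac is computed natively against a user-supplied newick tree
(polytomies and zero-length branches allowed; zero-length branches
contribute nothing).  For each non-root branch b with length l_b, let
p_X(b) be the fraction of sample X's total abundance descending through b:

- unweighted: Σ l_b·[present in exactly one sample] / Σ l_b·[present in
  at least one];
- weighted normalised: Σ l_b·|p_A − p_B| / Σ l_b·(p_A + p_B).

The weighted variant is the normalised one (bounded in [0, 1]) so both
modes are comparable; features with nonzero abundance missing from the
tree are an error that lists them.  Bray–Curtis and Jaccard are offered
for tree-free tables.

PCoA Gower-centres the squared distances, G = −½·J·D²·J, and
eigendecomposes; coordinates are eigenvectors scaled by √λ over positive
eigenvalues only, proportion explained is λ / Σλ⁺, and negative
eigenvalues are reported as diagnostics rather than silently dropped.

PERMANOVA uses the trace form: with the centred model matrix X (dummy
codes for categorical designs, centred column for a continuous covariate)
and hat matrix H, SS_model = tr(HGH), SS_total = tr(G),
R² = SS_model/SS_total, and pseudo-F uses model/residual degrees of
freedom.  This one formulation serves both the disease-factor test and
the per-covariate runs (each covariate marginally, mirroring how such
correction tables are usually reported).  p-values permute sample labels
with a seeded generator and the add-one convention
p = (1 + #{F_perm ≥ F}) / (1 + n_perm), so p is never zero; the default is
999 permutations.  A distance matrix with no variation (possible for
unweighted UniFrac when every taxon occurs in every sample) returns
F = 0, R² = 0, p = 1 with a warning rather than dividing by zero.

## Differential testing

Two-group tests are two-sided Wilcoxon rank-sum: exact null enumeration
when both groups have ≤ 8 samples and no ties, otherwise the tie-corrected
normal approximation **with** continuity correction — the correction keeps
the two branches within ~0.01 of each other at the branch boundary, so the
branch switch is statistically invisible.  The significance convention is
raw *P* < 0.01; Benjamini–Hochberg step-up adjustment is available because
clinical summary tables commonly report adjusted values.  Multi-timepoint
comparisons use tie-corrected Kruskal–Wallis (χ² reference).  Paired
two-timepoint comparisons default to the signed-rank test on
within-subject differences; the literal unpaired reading ("rank sum on two
timepoints") is available as `method="rank_sum"` since study descriptions
sometimes conflate the two.

## Reporter pathway scores

KO-level signed z-scores are z = Φ⁻¹(1 − p/2)·sign(effect), with p clipped
to [1e−15, 1−1e−15] (capping |z| at ≈ 7.94, so exact-zero p-values cannot
produce infinities).  A pathway with k scored member KOs gets
Z_raw = Σz/√k.  The background for each distinct k draws `n_background`
(default 1000) random size-k KO sets from all scored KOs — without
replacement within a set, independent across sets, seeded — giving μ_k and
σ_k, and Z_adj = (Z_raw − μ_k)/σ_k.  A degenerate background (σ_k at or
below float-noise scale relative to μ_k, e.g. a pathway equal to the full
KO universe) yields Z_adj = 0 with a flag instead of amplifying rounding
error.  The detection rule is |Z_adj| strictly greater than 2.3.  The
signed construction folds direction into a single score per pathway; the
reported direction label is the majority enriched-group among member KOs.

## Correlation networks

Spearman R is Pearson on average ranks, computed per pair over complete
observations (missing clinical values are dropped pairwise); entries with
fewer than `min_pairs = 5` complete pairs or a zero-variance margin are
absent rather than zero.  Edges require |R| strictly above the threshold
(default 0.4); there is no p-value gate, matching the threshold-only edge
rule such networks are typically drawn with.  Nodes keep their class
(MGS / metabolic / SCFA / gut–brain / sex hormone) and mean abundance;
isolated nodes are retained with a flag.  Raising the threshold can only
remove edges (monotonicity is property-tested).

## qPCR quantification

The standard curve is OLS of Ct on log₁₀ copies over ≥ 3 distinct
concentrations; slope must be negative, efficiency is
(10^(−1/slope) − 1)·100 so the dilution-doubling slope −1/log₁₀2 ≈ −3.3219
is exactly 100%.  Inversion: copies = 10^((Ct − intercept)/slope);
log CFU/g = log₁₀(copies · dilution / grams · cfu_per_copy).  The marker
copy number per genome (`cfu_per_copy`) defaults to 1 — a single-copy
strain-specific target — and is exposed because marker copy number is
assay-specific.  Cts outside the fitted standard range are flagged as
extrapolated.  Viability chemistry (PMA) and melting-curve QC are wet-lab
steps outside this package; an optional per-sample `passed_qc` flag is
honoured when present.  Colonization summaries report n / mean / sd of
log CFU/g per group × timepoint, with timepoints labelled baseline (A),
consumption (B, D, F) or washout (C, E, G).

## Synthetic study conditions

The generator emulates the study design with planted ground truth:

- **Community**: 20 + 20 samples (the deep-sequencing arm), 10 species
  with 20–100 genes each, gene lengths uniform in [300, 3000] nt,
  ~1e5 expected reads per sample.  Species k has latent per-sample
  loadings exp(σ·N(0,1)) (σ = 1), which *are* the planted co-abundance
  profiles; two species are depleted 4-fold and two enriched 4-fold in
  the case group.  Genes inherit their species profile times per-gene
  multiplicative lognormal noise (default sd 0.1) and counts are Poisson.
  Per-sample latent loadings — rather than group-level means — are what
  make species profiles mutually distinguishable at zero noise; with
  noise 0 and exact expected counts, within-species profiles are exactly
  collinear and canopy recovery is exact by construction.
- **KO/pathway layer**: 200 KOs hosted by species; two planted pathways
  of 20 KOs each drawn from the case-enriched species, 18 background
  pathways drawn uniformly; pathways reference only KOs some gene maps to.
- **Clinical variables**: anchored to published cohort-scale means/sds
  for realism of units (mmol/liter, IU/liter, pg/ml, μmol/g).  Coupled
  variables (SCFAs, PYY, ghrelin positive; LH, T negative) follow the
  standardised log abundance of a control-enriched species plus Gaussian
  noise (sd 0.5, Spearman |R| ≈ 0.85 at n = 40); uncoupled variables are
  pure anchored noise with **no** group offset — they are the negative
  controls for the network stage, and per-group anchoring would leak
  group structure into them.
- **Longitudinal arm**: 14 subjects (9 responders / 5 non-responders),
  timepoints A–G.  Responders colonize at Normal(6.93, 0.42) log CFU/g
  through consumption and washout; non-responders sit at the 2.0 log
  CFU/g detection floor plus half-normal jitter; Cts are back-computed
  through a slope −3.3219 / intercept 37 curve.  Responder trajectories
  carry a monotone LH decline (≈ −10 IU/liter over 10 weeks) and acetic
  acid rise (≈ +30 μmol/g).
- All randomness flows from one seed through independent spawned
  sub-streams, so every artefact is bit-reproducible.

What the synthetic benchmarks show — and what they do not: they establish
that each stage recovers the structure it targets when that structure is
present under lognormal–Poisson sampling, and that null calibrations
(PERMANOVA type-I error, Wilcoxon rejection rate, reporter tail rate) hold
at the stated sizes.  Real shotgun data adds strain mixtures, shared and
laterally transferred genes, compositional coupling between taxa, uneven
coverage and mapping artefacts; none of these are modelled, so passing the
benchmarks does not certify performance on real cohorts — it certifies the
implementation of the methods.

## Problem sizes and tolerances

Validation runs use sizes chosen to make the statistical checks sharp yet
quick: 1000 random matrices for the abundance oracle; 20 seeds at the
moderate-noise benchmark (gene noise sd 0.15, within-species profile
correlation ≈ 0.95) for clustering ARI; 500 random community/tree pairs
for UniFrac bounds; 500 null replicates (n = 20, 199 permutations) for
PERMANOVA type-I error; 1000 null features (20 + 20) for Wilcoxon
calibration; 2000 null pathways for the reporter tail; 100 seeds each for
planted-pathway ranking and network recovery; 200 replicates for
standard-curve slope recovery.  Exact identities (formula oracles,
round-trips) are asserted at 1e−9 or tighter; Monte-Carlo rates are
asserted within binomial confidence bands around their expected values.

## Known limitations

- Canopy clustering is O(genes × samples) per collection round with an
  O(canopies²) merge; it is comfortable at gene-catalog subsets (10³–10⁴
  genes) but would need blocking or approximate neighbour search at
  millions of genes.
- PERMANOVA supports one covariate per run (marginal models), not
  sequential multi-term designs.
- Taxonomy voting uses each gene's single best passing hit for lineages;
  genes with equally good hits to multiple genomes contribute only one.
- The generator's Poisson counts under-disperse relative to real
  metagenomes at low depth; species-level lognormal variation supplies
  the bulk of overdispersion, which is adequate for the rank-based tests
  used downstream but not for parametric count models.
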