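# Methods

This note documents the statistical procedures implemented in
`isoswitch`, the synthetic-data model used to exercise them, and the
design decisions taken where the underlying analysis recipe left
choices open.

## The isoform ratio and its partitions

The central statistic is the per-sample ratio of the short over the long
NF-YA isoform in TPM, computed as

    r = (TPM_short + c) / (TPM_long + c),   c = 0.01 TPM by default.

The pseudocount keeps samples with an undetected long isoform finite; at
0.01 TPM it is far below biologically meaningful expression and leaves
detected samples essentially untouched.  Two partitions are used:

- **Threshold classes** at cuts 1 and 5: low (r < 1), intermediate,
  high (r > 5).  The boundary values r = 1 and r = 5 are not covered by
  the open-interval definitions, so the implementation assigns them to
  the intermediate class (closed middle interval) and documents that
  choice rather than leaving it to floating-point accident.
- **Quartile cohorts** of a ranked cohort: bottom floor(n/4) samples
  (long-isoform dominant), top floor(n/4) (short-isoform dominant), the
  middle half as reference.  Boundary ties are broken by stable input
  order (logged); a constant ratio vector degenerates to all-intermediate
  with a warning.  With n = 345 the floor rule yields 86/173/86.

## Hypothesis tests

**Wilcoxon rank-sum.**  Unpaired two-group comparisons (tumor vs. normal,
predicted low- vs. high-ratio).  The exact null distribution is used when
`n_x·n_y ≤ 400` and the pooled sample is tie-free; otherwise the normal
approximation with midrank ties, tie-corrected variance and continuity
correction.  Identical multisets short-circuit to p = 1.  The unpaired
test is used throughout because the compared cohorts (tumors and normals)
are not matched pairs.

**Jonckheere–Terpstra.**  Ordered-trend alternative across the three
CIMP methylation classes.  J counts concordant between-group pairs
(half-weight for ties); the null moments are the classical no-ties forms
E[J] = (N² − Σn_i²)/4 and Var[J] = [N²(2N+3) − Σn_i²(2n_i+3)]/72.  With
ties present the default switches to a seeded permutation null (5000
resamples, add-one p estimate).  On tie-free data with group sizes ≥ 12
the normal and permutation p agree within 0.02 (tested).

**Benjamini–Hochberg.**  Step-up FDR with monotonicity enforcement; NaN
p-values propagate as NaN and are excluded from the ranking.

## Differential expression surrogate

The DEG stage reproduces the selection rule the downstream analyses
consume — FDR < 0.01 and |log2FC| > 2 — without depending on an external
DEG engine.  Counts are normalized by median-of-ratios size factors
(genes positive in all samples; total-count fallback otherwise; factors
scaled to geometric mean 1).  Fold change is
log2((mean_A + 1)/(mean_B + 1)) on normalized counts.

P-values come from a **moderated t-test**: per-gene pooled variances are
squeezed toward an empirical-Bayes prior (the prior degrees of freedom
and scale are estimated from the distribution of log sample variances by
the method of moments, with an inverse-trigamma Newton solve), and the t
statistic is referred to a t distribution with pooled-plus-prior degrees
of freedom.  This is the standard small-sample treatment for expression
data and is what makes the stage usable on a cell-line panel with 7 vs. 4
lines: a rank-sum test's smallest attainable two-sided p at those sizes
is 2/C(11,7) ≈ 0.006, which can never survive BH correction across
hundreds of genes at FDR < 0.01, whereas the moderated t retains
resolution.  A rank-sum variant (`test="wilcoxon"`) and ingestion of
externally computed tables (`read_deg_table`, DESeq2 column dialects)
are provided.

For the cell-line signature the default contrast pools low-ratio against
high-ratio lines; a `per_line` mode additionally requires the fold
change in every individual low-ratio line (the stricter reading of a
"commonly upregulated" gene list).  `common_deg` intersects any number
of DEG tables by direction.

## Centroid classification

Following the nearest-centroid scheme used for expression subtyping:
each gene is median-centered **across the cohort being classified**, and
each sample is assigned to the class whose reference profile it has the
highest Pearson correlation with.  Centering on the target cohort (not
the training cohort) is deliberate and matches how this subtyping
scheme is applied in the expression-profiling literature;
it makes predictions depend on cohort composition, which users should be
aware of when classifying small or skewed cohorts.  Ties in the argmax
are flagged (margin 0) rather than silently resolved; samples flat over
the shared genes are `unknown`.  Classification operates on
log2(TPM + 1) in the pipeline chains so that correlations are not
dominated by a few highly expressed genes.

The two-class ratio predictor builds a ±1 profile pair (+1 on the
up-signature, −1 on the down-signature, and its negation) and classifies
with the same machinery.  When the signature is one-sided the ±1 profile
is constant and Pearson correlation is undefined; the implementation
then scores each sample by its mean median-centered expression over the
signature genes (positive score over up-genes → low-ratio-like), which
is the natural degenerate limit of the correlation rule.

The **similar-medians filter** drops candidate signature genes whose
group medians (log2 scale) differ by less than δ between true low- and
high-ratio tumors; δ defaults to 1 log2 unit and is a CLI flag.  Published signature work discards such genes without stating a
quantitative rule; a
1-log2 cut reproduces the same order of attrition on synthetic panels
without claiming to be the original criterion.

Both classifiers are also exposed as scikit-learn estimators
(fit/predict, `get_params`, fitted attributes with trailing underscore)
so they compose with sklearn model selection; the module-level functions
are the primitives the estimators wrap.

## Promoter motif enrichment

Position frequency matrices (JASPAR text dialects, with or without
`A [ … ]` row brackets) are converted to log-odds with a pseudocount of
0.01 × column total per cell against a uniform background (overridable).
Each promoter (−450..+50 window, strand-oriented FASTA input) receives
the maximum log-odds over all offsets on both strands, min-max
normalized by the matrix's attainable extremes so a perfect consensus
site scores 1.  Windows containing N are invalid; promoters with no
valid window are excluded per matrix with a logged count.

Enrichment of a foreground gene set is a one-sided z-test on mean
normalized best-hit scores,

    z = (mean_fg − mean_bg) / (sd_bg / √n_fg),

with the background defaulting to all supplied promoters (the DEG
complement can be passed explicitly; promoter-scanning tools differ in
their background choice).  The background sd is the population sd,
making the test exactly invariant to duplicating the background.
Library rankings sort by p, ties by z.  Gene-set over-representation is
an upper-tail hypergeometric test with BH correction across sets.

The package ships synthetic fixture generators (`synthetic_ccaat_pwm`,
`synthetic_pwm_library`, `random_promoters`, `plant_motif`) — clearly
synthetic stand-ins, not database matrices — used by the tests and the
acceptance script to verify that a CCAAT box planted at −80 (the
canonical −60/−100 placement) makes the CCAAT matrix the library's top
hit.

## Survival analysis

Kaplan–Meier product-limit curves per ratio cohort with Greenwood
standard errors; the multi-group log-rank test; and Cox proportional
hazards with **Efron tie handling** — progression-free-interval times
come at day granularity, so ties are common and Breslow would bias
toward zero.  Categorical covariates are dummy-coded against explicitly
declared reference levels; the ratio-cohort reference is the
intermediate quartile band, and the subtype reference must be named by
the caller (published LUAD survival analyses are inconsistent between PI and
basal as the subtype baseline, so the package refuses to default it
silently).  Patients without PFI
records are excluded with a logged count.  The KM/log-rank/Cox
computations are delegated to `lifelines`; tests verify the Cox β
against an independently hand-coded Efron partial-likelihood grid search
to 3 decimals.

## The synthetic-data generator

`simulate_cohort` draws per-transcript baseline log2 means from a normal
(default mean 3, sd 2, in log2 counts), counts from a negative binomial
with variance m + αm² (α = 0.15), and TPM by library-size normalization
to 10⁶ (one shared effective length, so TPM columns sum to exactly 10⁶).
Planted structure, all configurable through `SimulationConfig`:

- **Isoform switch**: tumors shift NF-YAs by +1.0 log2 and NF-YAl by
  −0.5 log2 (free parameters chosen to mirror a strong but not extreme
  switch at the reported significance scale).
- **Latent ratio classes** (25/50/25): extra isoform offsets place the
  expected ratio below 1, between 1 and 5, or above 5; the realized
  ratio classes agree with the latent ones for essentially all non-
  boundary samples.
- **Subtypes** (TRU/PP/PI at 36/29/35%, the relative proportions of the
  TCGA LUAD cohort's 187/152/178 subtype split): three disjoint 40-gene blocks
  upregulated by 2 log2 in the owning subtype.
- **CIMP trend**: class k ∈ {0,1,2} adds k × 0.5 log2 to the short
  isoform's mean.
- **Ratio-linked block**: 30 genes upregulated by 3 log2 in low-ratio
  tumors and low-ratio cell lines (shared gene ids between cohort and
  panel, so a panel-derived signature transfers).
- **Survival**: exponential PFI times (baseline hazard 1/1500 per day,
  i.e. a median around 2.8 years) under proportional hazards on the
  realized ratio quartiles, with hazard ratios 1.83 (high) and 1.71
  (low) — the hazard ratios reported for LUAD ratio quartiles, doubling as
  generator truth for recovery tests.  Censoring is uniform on (0, u) with u
  solved so the expected censored fraction equals `censor_rate` (30%
  default); times are reported in whole days, which deliberately
  produces ties.

`simulate_cell_panel` mirrors the cohort's gene space with 7 low-, 15
intermediate- and 4 high-ratio lines (the ratio-class scale of a 26-line
LUAD cell panel).

What the generator does **not** emulate: batch effects, tumor purity,
gene–gene correlation beyond the planted blocks, length-variable
transcripts, paired tumor/normal designs, and non-proportional or
non-exponential hazards.  Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, at desk scale — not that the
original cohort-scale findings reproduce from public data, which would
require the deposited accessions.

## Numerical choices and degenerate inputs

- All randomness flows from a single integer seed per simulation; the
  same seed gives bit-identical outputs (tested), and every CLI output
  embeds the seed and a config hash.
- Exact vs. asymptotic switches: rank-sum at n_x·n_y ≤ 400 (tie-free);
  Jonckheere permutation under ties.
- Zero-variance samples, empty groups, all-censored cohorts, all-zero
  genes, constant ratio vectors and one-sided signatures all have
  defined, logged behavior rather than NaN propagation (see the module
  docstrings and tests).
- The empirical-Bayes variance moderation degenerates gracefully: with
  fewer than 3 informative genes it falls back to the plain pooled t;
  when sample variances are more concentrated than a chi-square of the
  pooled df the prior df is infinite and a common variance is used.

## Known limitations

- The DEG stage is a surrogate with the right selection thresholds and
  small-sample behavior, not a negative-binomial GLM; dispersion
  shrinkage and Wald/LRT machinery are out of scope (import a DESeq2
  table for exact parity).
- Promoter windows are consumed as already-extracted, strand-oriented
  FASTA; genome arithmetic is out of scope.
- Proportional-hazards diagnostics are limited to what lifelines
  provides; time-varying covariates and competing risks are not modeled.
- The quartile partition uses ratio magnitude to name the extreme
  cohorts; if an input cohort's ratio distribution is degenerate the
  partition collapses to the reference band by design.
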