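# isoswitch

**NF-YA splice-isoform ratio analysis for lung adenocarcinoma RNA-Seq cohorts.**

The transcription factor NF-Y binds the CCAAT box, a promoter element
recurrently enriched upstream of genes overexpressed in cancer.  Its
regulatory subunit NF-YA is expressed as two major splice isoforms — a
"short" form (NF-YAs) and a "long" form (NF-YAl) that differ by 28 amino
acids in the trans-activation domain.  In lung adenocarcinoma (LUAD),
bulk RNA-Seq shows an isoform switch: NF-YAs rises and NF-YAl falls in
tumors, and patients in *either* extreme of the per-sample ratio

    r = TPM(NF-YAs) / TPM(NF-YAl)

have worse progression-free intervals than patients with intermediate
ratios.  `isoswitch` packages the full analysis chain behind that kind of
study as tested, reusable components:

- **Expression IO** — RSEM-style isoform/gene TSV tables, sample
  metadata, GMT gene sets, gene × class centroid tables.
- **Ratio partitioning** — threshold classes (low: r < 1, intermediate:
  1 ≤ r ≤ 5, high: r > 5) and quartile cohorts (bottom 25% /
  middle 50% / top 25% of ranked ratios).
- **Statistics** — Wilcoxon rank-sum (exact for small groups),
  Jonckheere–Terpstra ordered-trend test with a seeded permutation
  option, Benjamini–Hochberg FDR.
- **Differential expression** — a self-contained surrogate stage:
  median-of-ratios normalization and a moderated t-test
  (empirical-Bayes variance shrinkage), selecting genes at FDR < 0.01
  and |log2FC| > 2; external DESeq2-style tables can be imported instead.
- **Centroid classification** — median-centered Pearson nearest-centroid
  assignment, both for extending molecular-subtype labels (TRU/PP/PI)
  to a whole cohort and for predicting a tumor's ratio class from a
  cell-line-derived gene signature.  Exposed as scikit-learn estimators
  (`MedianCentroidClassifier`, `SignatureRatioClassifier`).
- **Promoter motif enrichment** — Pscan-style scanning of JASPAR-format
  position frequency matrices over promoter windows (−450..+50 from the
  TSS) with a one-sided z-test on best-hit scores, plus hypergeometric
  over-representation over GMT collections.
- **Survival** — Kaplan–Meier curves, log-rank test, and Cox
  proportional hazards (Efron ties) with explicit reference levels,
  stratified by ratio quartile.
- **Synthetic data** — a negative-binomial cohort/cell-panel generator
  that plants the isoform switch, latent subtypes, a CIMP trend, a
  ratio-linked signature block, and quartile-dependent hazards, so the
  entire chain is testable without downloads.

## Worked example

```python
from isoswitch import (SimulationConfig, simulate_cohort, simulate_cell_panel,
                       run_tumor_normal, run_signature_workflow, run_survival)

cfg = SimulationConfig(seed=0)          # 300 tumors, 60 normals, 1000 genes
iso, meta, truth = simulate_cohort(cfg)

res = run_tumor_normal(iso, meta)
print(res["tests"][["U", "z", "pvalue", "median_shift"]].round(3))

panel, classes, planted = simulate_cell_panel(cfg)   # 7 low / 15 int / 4 high lines
sig = run_signature_workflow(panel, iso, meta)
print(f"signature: {len(sig['signature_up'])} up genes, "
      f"{len(sig['retained_up'])} retained after the median filter")
print(f"ratio separation across predicted classes: p = {sig['validation'].pvalue:.3g}")

surv = run_survival(iso, meta, references={"stage": "I", "gender": "female",
                                           "subtype": "PI"})
print(surv["cox"].summary.loc[["cohort=NF-YAs_high", "cohort=NF-YAl_high"],
                              ["hr", "ci_low", "ci_high", "pvalue"]].round(3))
print(f"log-rank: chi2 = {surv['logrank']['chi2']:.2f}, p = {surv['logrank']['p']:.3g}")
```

prints

```
                   U      z  pvalue  median_shift
feature
NFYA (gene)  13301.0  5.844     0.0      3154.820
NFYA-s       12319.0  4.510     0.0      3859.936
NFYA-l        6034.0 -4.030     0.0     -1092.286
ratio        12539.0  4.809     0.0         2.455
signature: 29 up genes, 29 retained after the median filter
ratio separation across predicted classes: p = 1.19e-38
                       hr  ci_low  ci_high  pvalue
covariate
cohort=NF-YAs_high  1.735   1.236    2.436   0.001
cohort=NF-YAl_high  2.565   1.814    3.626   0.000
log-rank: chi2 = 30.92, p = 1.93e-07
```

Reading this: the simulated tumors show the isoform switch (short isoform
up, long isoform down, ratio increased, all with tiny rank-sum p-values);
the cell-line-derived up-signature transfers to the cohort and separates
tumors by their measured ratio; and both extreme ratio quartiles carry a
significantly elevated progression hazard relative to the intermediate
band (hazard ratios 1.7–2.6 here; the generator plants 1.83 and 1.71, and
a 300-patient cohort estimates them with this much spread).

A `click` CLI mirrors the library (`isoswitch simulate / io / ratio /
deg / classify / signature / motifs / cimp / survival / report`); every
output TSV embeds the seed and a config hash, and reruns with the same
seed are bit-identical.

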