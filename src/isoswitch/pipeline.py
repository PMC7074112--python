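"""End-to-end analysis chains over in-memory objects.

Each ``run_*`` function is a pure orchestration of the library modules;
the CLI wraps them with file IO.  The chains mirror the study's analyses:
tumor/normal subunit comparison, subtype extension by centroid
classification, the cell-line signature workflow, the CIMP ordered-trend
test, ratio-quartile survival, and promoter motif enrichment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import centroid as ct
from . import deg as deg_mod
from . import motifs as mt
from .io import GeneMatrix, IsoformMatrix, collapse_to_gene
from .ratios import QUARTILE_LABELS, compute_ratio, partition_samples, quartile_stratify
from .stats import bh_fdr, jonckheere_trend, wilcoxon_ranksum
from .survival import cox_fit, km_estimate, logrank

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_tumor_normal",
    "run_subtype_extension",
    "run_signature_workflow",
    "run_cimp_trend",
    "run_survival",
    "run_motifs",
]


@dataclass
class RunConfig:
    """Pipeline thresholds and provenance fields.

    Defaults are the reference thresholds: DEG selection at FDR < 0.01
    and |log2FC| > 2, ratio partition cuts at 1 and 5, signature filter
    δ = 1 log2 unit.
    """

    alpha: float = 0.01
    fc_min: float = 2.0
    ratio_low_cut: float = 1.0
    ratio_high_cut: float = 5.0
    filter_delta: float = 1.0
    ratio_pseudocount: float = 0.01
    short_tx: str = "NFYA-s"
    long_tx: str = "NFYA-l"
    nfya_gene: str = "NFYA"
    seed: int = 0
    out_dir: str = "isoswitch_out"
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "fc_min", "ratio_low_cut", "ratio_high_cut", "filter_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ratio_low_cut >= self.ratio_high_cut:
            raise ValueError("ratio_low_cut must be below ratio_high_cut")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"seed={self.seed}", f"config_sha={self.digest}"]


def _tumor_normal_ids(meta: pd.DataFrame) -> tuple[list[str], list[str]]:
    tumors = list(meta.index[meta["tissue"] == "tumor"])
    normals = list(meta.index[meta["tissue"] == "normal"])
    if not tumors or not normals:
        raise ValueError("need both tumor and normal samples")
    return tumors, normals


def run_tumor_normal(iso: IsoformMatrix, meta: pd.DataFrame,
                     cfg: RunConfig | None = None) -> dict:
    """Tumor-vs-normal comparison of NF-YA at gene, isoform and ratio level.

    Returns ``tests`` (one Wilcoxon row per feature with BH q-values) and
    the per-sample ratio partition.
    """
    cfg = cfg or RunConfig()
    tumors, normals = _tumor_normal_ids(meta.loc[meta.index.intersection(iso.samples)])
    genes = collapse_to_gene(iso)
    part = partition_samples(iso, cfg.short_tx, cfg.long_tx, cfg.ratio_pseudocount)

    features: dict[str, pd.Series] = {}
    if cfg.nfya_gene in genes.values.index:
        features[f"{cfg.nfya_gene} (gene)"] = genes.values.loc[cfg.nfya_gene]
    features[cfg.short_tx] = iso.tpm.loc[cfg.short_tx]
    features[cfg.long_tx] = iso.tpm.loc[cfg.long_tx]
    features["ratio"] = part["ratio"]

    rows = []
    for name, values in features.items():
        res = wilcoxon_ranksum(values[tumors], values[normals])
        delta = float(np.median(values[tumors]) - np.median(values[normals]))
        rows.append({"feature": name, "U": res.statistic, "z": res.z,
                     "pvalue": res.pvalue, "median_shift": delta})
    tests = pd.DataFrame(rows).set_index("feature")
    tests["qvalue"] = bh_fdr(tests["pvalue"].to_numpy())
    return {"tests": tests, "ratios": part}


def run_subtype_extension(
    iso: IsoformMatrix,
    meta: pd.DataFrame,
    centroids: ct.CentroidSet | pd.DataFrame | None = None,
    cfg: RunConfig | None = None,
) -> dict:
    """Extend subtype labels to all tumors by nearest-centroid classification.

    ``centroids`` may be a published gene × class profile table; when
    omitted, centroids are rebuilt from the metadata's labeled tumors.
    Emits per-subtype isoform statistics and the subtype × ratio-class
    cross-tabulation.
    """
    cfg = cfg or RunConfig()
    genes = collapse_to_gene(iso)
    tumors, normals = _tumor_normal_ids(meta.loc[meta.index.intersection(iso.samples)])
    # correlation-based classification operates on log2(TPM + 1)
    tumor_expr = np.log2(genes.values[tumors] + 1.0)

    if centroids is None:
        labeled = [s for s in tumors if meta.loc[s, "subtype"] != "unknown"]
        if len(labeled) < 6:
            raise ValueError("no centroid table and too few labeled tumors to build one")
        centroids = ct.build_centroid(tumor_expr[labeled], meta.loc[labeled, "subtype"])
    elif isinstance(centroids, pd.DataFrame):
        centroids = ct.CentroidSet(centroids)

    assignments = ct.classify(tumor_expr, centroids)
    part = partition_samples(iso, cfg.short_tx, cfg.long_tx, cfg.ratio_pseudocount)

    rows = []
    for st in centroids.classes:
        members = assignments.index[assignments["class"] == st]
        if len(members) == 0:
            continue
        for name, values in ((cfg.short_tx, iso.tpm.loc[cfg.short_tx]),
                             (cfg.long_tx, iso.tpm.loc[cfg.long_tx]),
                             ("ratio", part["ratio"])):
            res = wilcoxon_ranksum(values[members], values[normals])
            rows.append({"subtype": st, "feature": name, "n": len(members),
                         "U": res.statistic, "z": res.z, "pvalue": res.pvalue})
    per_subtype = pd.DataFrame(rows)

    crosstab = pd.crosstab(assignments["class"], part.loc[tumors, "tri_class"])
    return {"assignments": assignments, "per_subtype_tests": per_subtype,
            "crosstab": crosstab, "ratios": part}


def _per_line_up(counts: pd.DataFrame, low_lines: Sequence[str],
                 high_lines: Sequence[str], fc_min: float, pc: float = 1.0) -> set[str]:
    """Genes whose per-line log2FC over the mean of high lines exceeds
    fc_min in every low-ratio line."""
    factors = deg_mod.size_factors(counts[list(low_lines) + list(high_lines)])
    norm = counts.div(factors, axis=1)
    high_mean = norm[list(high_lines)].mean(axis=1)
    ok = pd.Series(True, index=counts.index)
    for line in low_lines:
        lfc = np.log2(norm[line] + pc) - np.log2(high_mean + pc)
        ok &= lfc > fc_min
    return set(counts.index[ok])


def run_signature_workflow(
    panel_iso: IsoformMatrix,
    cohort_iso: IsoformMatrix,
    cohort_meta: pd.DataFrame,
    cfg: RunConfig | None = None,
    mode: str = "pooled",
) -> dict:
    """Cell-line-derived ratio signature applied to a tumor cohort.

    Steps: partition the panel by isoform ratio; differential expression
    of low- vs. high-ratio lines (gene-level counts, FDR/fold-change
    thresholds); optionally require the fold-change in every low line
    (``mode="per_line"``); discard signature genes whose tumor medians are
    similar between real low- and high-ratio tumors; predict each tumor's
    ratio class from the surviving up/down signature; validate with a
    rank-sum test of the measured ratio across predicted classes.
    """
    cfg = cfg or RunConfig()
    if panel_iso.counts is None:
        raise ValueError("panel needs counts for the DEG stage")
    panel_part = compute_ratio(panel_iso, cfg.short_tx, cfg.long_tx, cfg.ratio_pseudocount)
    low_lines = list(panel_part.index[panel_part["tri_class"] == "low"])
    high_lines = list(panel_part.index[panel_part["tri_class"] == "high"])
    if len(low_lines) < 2 or len(high_lines) < 2:
        raise ValueError(
            f"panel has {len(low_lines)} low- and {len(high_lines)} high-ratio lines; need ≥ 2 each")

    panel_counts = collapse_to_gene_counts(panel_iso)
    deg = deg_mod.differential_expression(panel_counts, low_lines, high_lines,
                                          alpha=cfg.alpha, fc_min=cfg.fc_min)
    up = list(deg.index[deg["direction"] == "up"])
    down = list(deg.index[deg["direction"] == "down"])
    if mode == "per_line":
        keep = _per_line_up(panel_counts, low_lines, high_lines, cfg.fc_min)
        up = [g for g in up if g in keep]
    elif mode != "pooled":
        raise ValueError(f"unknown mode {mode!r}")
    up = [g for g in up if g != cfg.nfya_gene]
    if not up:
        raise ValueError("no upregulated signature genes at the configured thresholds")

    cohort_genes = collapse_to_gene(cohort_iso)
    tumors = [s for s in cohort_iso.samples
              if cohort_meta.loc[s, "tissue"] == "tumor"] if "tissue" in cohort_meta else \
        list(cohort_iso.samples)
    tumor_expr = cohort_genes.values[tumors]
    cohort_part = compute_ratio(cohort_iso, cfg.short_tx, cfg.long_tx, cfg.ratio_pseudocount)
    tri = cohort_part.loc[tumors, "tri_class"]
    extreme = tri[tri.isin(["low", "high"])]

    retained, deltas = ct.filter_uninformative(tumor_expr, up, extreme, delta=cfg.filter_delta)
    if len(retained) < 2:
        raise ValueError("signature empty after the similar-medians filter")
    down_retained = [g for g in down if g in tumor_expr.index]

    prediction = ct.two_class_from_signature(np.log2(tumor_expr + 1.0), retained, down_retained)
    pred = prediction["class"]
    low_like = cohort_part.loc[pred.index[pred == "low_ratio_like"], "ratio"]
    high_like = cohort_part.loc[pred.index[pred == "high_ratio_like"], "ratio"]
    if len(low_like) and len(high_like):
        validation = wilcoxon_ranksum(low_like, high_like)
    else:
        validation = None
        logger.warning("signature workflow: a predicted class is empty; no validation test")

    crosstab = None
    if "subtype" in cohort_meta.columns:
        crosstab = pd.crosstab(cohort_meta.loc[pred.index, "subtype"], pred)
    return {
        "panel_partition": panel_part,
        "deg": deg,
        "signature_up": up,
        "signature_down": down,
        "retained_up": retained,
        "filter_deltas": deltas,
        "prediction": prediction,
        "validation": validation,
        "crosstab": crosstab,
    }


def collapse_to_gene_counts(iso: IsoformMatrix) -> pd.DataFrame:
    """Gene-level expected counts by summing member transcripts."""
    if iso.counts is None:
        raise ValueError("matrix has no counts")
    return iso.counts.groupby(iso.gene_of_transcript.loc[iso.counts.index]).sum()


def run_cimp_trend(iso: IsoformMatrix, meta: pd.DataFrame,
                   cfg: RunConfig | None = None) -> pd.DataFrame:
    """Ordered-trend tests of NF-YA features across CIMP low→int→high."""
    cfg = cfg or RunConfig()
    genes = collapse_to_gene(iso)
    part = compute_ratio(iso, cfg.short_tx, cfg.long_tx, cfg.ratio_pseudocount)
    tumors = meta.index[(meta["tissue"] == "tumor") & (meta["cimp"] != "unknown")]
    tumors = tumors.intersection(iso.samples)
    if len(tumors) == 0:
        raise ValueError("no tumors with CIMP labels")
    order = ["low", "intermediate", "high"]
    cimp = meta.loc[tumors, "cimp"]

    features = {
        f"{cfg.nfya_gene} (gene)": genes.values.loc[cfg.nfya_gene],
        cfg.short_tx: iso.tpm.loc[cfg.short_tx],
        cfg.long_tx: iso.tpm.loc[cfg.long_tx],
        "ratio": part["ratio"],
    }
    rows = []
    for name, values in features.items():
        groups = [values[cimp.index[cimp == c]].to_numpy() for c in order]
        if any(len(g) == 0 for g in groups):
            logger.warning("run_cimp_trend: empty CIMP class for %s; skipped", name)
            continue
        res = jonckheere_trend(groups, seed=cfg.seed)
        rows.append({"feature": name, "J": res.statistic, "z": res.z,
                     "p_one_sided": res.p_one_sided, "p_two_sided": res.p_two_sided})
    return pd.DataFrame(rows).set_index("feature")


def run_survival(
    iso: IsoformMatrix,
    meta: pd.DataFrame,
    cfg: RunConfig | None = None,
    covariates: Sequence[str] = ("stage", "gender", "subtype"),
    references: Mapping[str, str] | None = None,
) -> dict:
    """Ratio-quartile PFI analysis: KM curves, log-rank, Cox PH.

    ``references`` must name the reference level for every categorical
    covariate (the ratio cohort reference defaults to the intermediate
    quartile band).  Patients without PFI records are excluded with a
    logged count.
    """
    cfg = cfg or RunConfig()
    part = compute_ratio(iso, cfg.short_tx, cfg.long_tx, cfg.ratio_pseudocount)
    tumors = [s for s in iso.samples if meta.loc[s, "tissue"] == "tumor"]
    with_pfi = [s for s in tumors if pd.notna(meta.loc[s, "pfi_time"])
                and pd.notna(meta.loc[s, "pfi_event"])]
    n_missing = len(tumors) - len(with_pfi)
    if n_missing:
        logger.info("run_survival: %d tumors without PFI excluded", n_missing)
    if len(with_pfi) < 8:
        raise ValueError("too few patients with PFI records")

    cohort = quartile_stratify(part.loc[with_pfi, "ratio"])
    times = meta.loc[with_pfi, "pfi_time"].to_numpy(dtype=float)
    events = meta.loc[with_pfi, "pfi_event"].to_numpy(dtype=float)

    km = km_estimate(times, events, cohort)
    chi2, df, p = logrank(times, events, cohort)

    data = pd.DataFrame({"time": times, "event": events, "cohort": cohort.to_numpy()},
                        index=with_pfi)
    categorical = {"cohort": QUARTILE_LABELS[1]}
    refs = dict(references or {})
    for cov in covariates:
        levels = meta.loc[with_pfi, cov].astype(str)
        usable = levels != "unknown"
        if levels[usable].nunique() < 2:
            logger.warning("run_survival: covariate %r has < 2 levels; dropped", cov)
            continue
        if cov not in refs:
            raise ValueError(f"reference level for covariate {cov!r} must be declared")
        data[cov] = levels.where(usable)
        categorical[cov] = refs[cov]
    cox = cox_fit(data, "time", "event", categorical=categorical)
    return {"cohorts": cohort, "km": km, "logrank": {"chi2": chi2, "df": df, "p": p},
            "cox": cox}


def run_motifs(
    fg_genes: Sequence[str],
    promoters: Mapping[str, str],
    pwms: Sequence[mt.PWMatrix],
    bg_genes: Sequence[str] | None = None,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Promoter PWM enrichment of a foreground set, plus optional ORA."""
    ranking = mt.rank_motifs(fg_genes, promoters, pwms, bg_genes)
    ora = None
    if gene_sets:
        universe = list(promoters)
        ora = mt.ora_table(fg_genes, gene_sets, universe)
    return {"motif_ranking": ranking, "ora": ora}
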