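"""Synthetic RNA-Seq cohorts with the statistical structure the analysis assumes.

The generator emulates, at configurable scale:

* tumor/normal transcript-level expression in which the short NF-YA
  isoform rises and the long one falls in tumors (the isoform switch);
* three latent expression subtypes (TRU/PP/PI) carried by disjoint
  signature-gene blocks;
* a latent low/intermediate/high isoform-ratio class per tumor, with a
  ratio-linked gene block upregulated in low-ratio tumors;
* a monotone short-isoform trend across three CpG-methylator (CIMP)
  classes;
* a small cell-line panel with the same gene space and the same planted
  low-ratio block;
* progression-free-interval records whose hazard is elevated in both
  extreme ratio quartiles.

Counts are negative-binomial with gene-wise mean and a common dispersion
(variance m + α m²); TPM is obtained by library-size normalization to
one million (all transcripts share one effective length).  All randomness
flows from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import IsoformMatrix
from .ratios import QUARTILE_LABELS, quartile_stratify

__all__ = ["SimulationConfig", "simulate_cohort", "simulate_cell_panel", "simulate_survival"]

SHORT_TX = "NFYA-s"
LONG_TX = "NFYA-l"
NFYA_GENE = "NFYA"

SUBTYPES = ("TRU", "PP", "PI")
CIMP_CLASSES = ("low", "intermediate", "high")
RATIO_CLASSES = ("low", "intermediate", "high")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Cohort scale mirrors the analyzed data at desk size (tumor/normal
    roughly 5:1, subtype proportions 36/29/35).  The hazard ratios of the
    extreme ratio quartiles (1.83 high, 1.71 low vs. intermediate) are the
    reported clinical effect sizes and double as generator truth.
    """

    n_tumor: int = 300
    n_normal: int = 60
    n_genes: int = 1000
    subtype_props: tuple[float, float, float] = (0.36, 0.29, 0.35)
    cimp_props: tuple[float, float, float] = (0.35, 0.45, 0.20)
    ratio_class_props: tuple[float, float, float] = (0.25, 0.50, 0.25)
    #: tumor-wide log2 shifts of the two NF-YA isoforms (the switch)
    nfyas_tumor_log2_shift: float = 1.0
    nfyal_tumor_log2_shift: float = -0.5
    #: extra (short, long) log2 offsets for the latent low/high ratio classes
    low_ratio_extra_log2: tuple[float, float] = (-2.5, 1.5)
    high_ratio_extra_log2: tuple[float, float] = (1.8, -0.8)
    #: per-CIMP-class log2 increment of the short isoform (class index 0,1,2)
    cimp_trend_slope: float = 0.5
    #: subtype signature blocks: size and log2 upshift in the owning subtype
    signature_block_size: int = 40
    signature_log2_shift: float = 2.0
    #: ratio-linked block: upregulated in low-ratio tumors and cell lines
    ratio_block_size: int = 30
    ratio_block_log2_shift: float = 3.0
    #: negative-binomial dispersion α (variance = m + α m²)
    nb_dispersion: float = 0.15
    base_log2_mean: float = 3.0
    base_log2_sd: float = 2.0
    nfya_base_log2: float = 6.0
    #: survival: exponential baseline, proportional hazards on ratio quartiles
    hr_high: float = 1.83
    hr_low: float = 1.71
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    censor_rate: float = 0.30
    #: cell-line panel class sizes (low, intermediate, high ratio)
    panel_sizes: tuple[int, int, int] = (7, 15, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subtype_props", "cimp_props", "ratio_class_props"):
            p = getattr(self, name)
            if len(p) != 3 or abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError(f"{name} must be 3 non-negative proportions summing to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.hr_high <= 0 or self.hr_low <= 0:
            raise ValueError("hazard ratios must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_genes < 3 * self.signature_block_size + self.ratio_block_size + 1:
            raise ValueError("n_genes too small for the configured signature blocks")

    def null(self) -> "SimulationConfig":
        """Copy of the config with every planted effect removed."""
        return replace(
            self,
            nfyas_tumor_log2_shift=0.0,
            nfyal_tumor_log2_shift=0.0,
            low_ratio_extra_log2=(0.0, 0.0),
            high_ratio_extra_log2=(0.0, 0.0),
            cimp_trend_slope=0.0,
            signature_log2_shift=0.0,
            ratio_block_log2_shift=0.0,
            hr_high=1.0,
            hr_low=1.0,
        )


def _gene_table(cfg: SimulationConfig) -> tuple[list[str], pd.Series, dict]:
    """Transcript ids, transcript→gene map, and planted block membership."""
    b = cfg.signature_block_size
    blocks = {st: [f"SIG-{st}-{i:03d}" for i in range(b)] for st in SUBTYPES}
    ratio_block = [f"RSIG-{i:03d}" for i in range(cfg.ratio_block_size)]
    n_bg = cfg.n_genes - 3 * b - cfg.ratio_block_size - 1
    background = [f"G{i:04d}" for i in range(n_bg)]
    genes = [*blocks["TRU"], *blocks["PP"], *blocks["PI"], *ratio_block, *background]
    transcripts = [SHORT_TX, LONG_TX] + [f"{g}.1" for g in genes]
    gene_of_tx = pd.Series(
        [NFYA_GENE, NFYA_GENE] + genes, index=transcripts, dtype=object
    )
    return transcripts, gene_of_tx, {"subtype_blocks": blocks, "ratio_block": ratio_block}


def _nb_draw(mean: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def _tpm_from_counts(counts: np.ndarray) -> np.ndarray:
    colsum = counts.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return counts / colsum * 1e6


def simulate_survival(
    cohorts: Sequence[str],
    hr_high: float = 1.83,
    hr_low: float = 1.71,
    baseline_hazard: float = 1.0 / 1500.0,
    censor_rate: float = 0.30,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Exponential PFI times under proportional hazards on ratio cohorts.

    ``cohorts`` holds one of the quartile labels per patient; hazards are
    ``baseline · hr_low`` / ``baseline`` / ``baseline · hr_high`` for the
    low / intermediate / high cohort.  Censoring times are uniform on
    (0, u) with u chosen so the expected censored fraction equals
    ``censor_rate``.  Times are reported in whole days (≥ 1).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cohorts = pd.Series(list(cohorts))
    hr = {QUARTILE_LABELS[0]: hr_low, QUARTILE_LABELS[1]: 1.0, QUARTILE_LABELS[2]: hr_high}
    lam = baseline_hazard * cohorts.map(hr).to_numpy(dtype=float)
    t = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        # P(censored) = P(C < T) = (1 - e^{-λu}) / (λu) for C ~ U(0, u)
        def cens_frac(u: float) -> float:
            return float(np.mean((1 - np.exp(-lam * u)) / (lam * u))) - censor_rate
        u = brentq(cens_frac, 1e-9, 1e12)
        c = rng.uniform(0, u, size=len(lam))
    else:
        c = np.full(len(lam), np.inf)
    time = np.maximum(1, np.ceil(np.minimum(t, c))).astype(int)
    event = (t <= c).astype(int)
    return pd.DataFrame({"time": time, "event": event, "cohort": cohorts.to_numpy()})


def _isoform_offsets(cfg: SimulationConfig, ratio_class: np.ndarray,
                     cimp_idx: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample log2 offsets of the short and long isoform."""
    short = np.full(ratio_class.shape, cfg.nfyas_tumor_log2_shift)
    long = np.full(ratio_class.shape, cfg.nfyal_tumor_log2_shift)
    short[ratio_class == "low"] += cfg.low_ratio_extra_log2[0]
    long[ratio_class == "low"] += cfg.low_ratio_extra_log2[1]
    short[ratio_class == "high"] += cfg.high_ratio_extra_log2[0]
    long[ratio_class == "high"] += cfg.high_ratio_extra_log2[1]
    if cimp_idx is not None:
        short = short + cfg.cimp_trend_slope * cimp_idx
    return short, long


def simulate_cohort(cfg: SimulationConfig) -> tuple[IsoformMatrix, pd.DataFrame, dict]:
    """Simulate a tumor/normal cohort.

    Returns the isoform matrix (TPM + counts), a metadata table in the
    package's dialect (tissue, subtype, cimp, stage, gender, PFI), and a
    truth dict with the latent labels, planted gene blocks, and the
    per-transcript negative-binomial means.
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts, gene_of_tx, planted = _gene_table(cfg)
    n = cfg.n_tumor + cfg.n_normal
    samples = [f"T{i:04d}" for i in range(cfg.n_tumor)] + [f"N{i:04d}" for i in range(cfg.n_normal)]
    is_tumor = np.array([True] * cfg.n_tumor + [False] * cfg.n_normal)

    # latent labels for tumors
    subtype = rng.choice(SUBTYPES, size=cfg.n_tumor, p=cfg.subtype_props)
    cimp = rng.choice(CIMP_CLASSES, size=cfg.n_tumor, p=cfg.cimp_props)
    cimp_idx = np.array([CIMP_CLASSES.index(c) for c in cimp], dtype=float)
    ratio_class = rng.choice(RATIO_CLASSES, size=cfg.n_tumor, p=cfg.ratio_class_props)

    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=len(transcripts))
    base[0] = base[1] = cfg.nfya_base_log2
    log2_mean = np.tile(base[:, None], (1, n))

    t_short, t_long = _isoform_offsets(cfg, ratio_class, cimp_idx)
    log2_mean[0, :cfg.n_tumor] += t_short
    log2_mean[1, :cfg.n_tumor] += t_long

    tx_index = pd.Index(transcripts)
    for st, genes in planted["subtype_blocks"].items():
        rows = tx_index.get_indexer([f"{g}.1" for g in genes])
        cols = np.where(subtype == st)[0]
        log2_mean[np.ix_(rows, cols)] += cfg.signature_log2_shift
    rrows = tx_index.get_indexer([f"{g}.1" for g in planted["ratio_block"]])
    rcols = np.where(ratio_class == "low")[0]
    log2_mean[np.ix_(rrows, rcols)] += cfg.ratio_block_log2_shift

    nb_mean = 2.0**log2_mean
    counts = _nb_draw(nb_mean, cfg.nb_dispersion, rng)
    tpm = _tpm_from_counts(counts)

    iso = IsoformMatrix(
        pd.DataFrame(tpm, index=tx_index, columns=samples),
        gene_of_tx,
        counts=pd.DataFrame(counts, index=tx_index, columns=samples),
    )

    # realized ratio quartiles among tumors drive the planted hazards
    tumor_ids = samples[: cfg.n_tumor]
    tpm_s = iso.tpm.loc[SHORT_TX, tumor_ids]
    tpm_l = iso.tpm.loc[LONG_TX, tumor_ids]
    realized_ratio = (tpm_s + 0.01) / (tpm_l + 0.01)
    cohort = quartile_stratify(realized_ratio)
    surv = simulate_survival(cohort, cfg.hr_high, cfg.hr_low, cfg.baseline_hazard,
                             cfg.censor_rate, rng)

    meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    meta["tissue"] = np.where(is_tumor, "tumor", "normal")
    meta["subtype"] = "unknown"
    meta.loc[tumor_ids, "subtype"] = subtype
    meta["cimp"] = "unknown"
    meta.loc[tumor_ids, "cimp"] = cimp
    meta["stage"] = "unknown"
    meta.loc[tumor_ids, "stage"] = rng.choice(
        ["I", "II", "III", "IV"], size=cfg.n_tumor, p=[0.55, 0.25, 0.15, 0.05]
    )
    meta["gender"] = rng.choice(["female", "male"], size=n)
    meta["pfi_time"] = np.nan
    meta["pfi_event"] = np.nan
    meta.loc[tumor_ids, "pfi_time"] = surv["time"].to_numpy(dtype=float)
    meta.loc[tumor_ids, "pfi_event"] = surv["event"].to_numpy(dtype=float)

    truth_samples = pd.DataFrame(index=pd.Index(tumor_ids, name="sample_id"))
    truth_samples["subtype"] = subtype
    truth_samples["cimp"] = cimp
    truth_samples["ratio_class"] = ratio_class
    truth_samples["quartile_cohort"] = cohort.to_numpy()
    truth = {
        "samples": truth_samples,
        "subtype_blocks": planted["subtype_blocks"],
        "ratio_block": planted["ratio_block"],
        "nb_mean": pd.DataFrame(nb_mean, index=tx_index, columns=samples),
        "config": cfg,
    }
    return iso, meta, truth


def simulate_cell_panel(cfg: SimulationConfig) -> tuple[IsoformMatrix, pd.Series, list[str]]:
    """Simulate the cell-line panel: low/intermediate/high ratio classes with
    the ratio-linked block upregulated only in low-ratio lines.

    The gene space is shared with :func:`simulate_cohort` so a signature
    derived from the panel transfers to the cohort.  Returns the isoform
    matrix, the true ratio class per line, and the planted gene list.
    """
    if min(cfg.panel_sizes) < 2:
        raise ValueError("each panel ratio class needs at least 2 cell lines")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    transcripts, gene_of_tx, planted = _gene_table(cfg)
    n_low, n_int, n_high = cfg.panel_sizes
    n = n_low + n_int + n_high
    classes = np.array(["low"] * n_low + ["intermediate"] * n_int + ["high"] * n_high)
    lines = [f"CL{i:02d}" for i in range(n)]

    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=len(transcripts))
    base[0] = base[1] = cfg.nfya_base_log2
    log2_mean = np.tile(base[:, None], (1, n))
    p_short, p_long = _isoform_offsets(cfg, classes, None)
    log2_mean[0] += p_short
    log2_mean[1] += p_long

    tx_index = pd.Index(transcripts)
    rrows = tx_index.get_indexer([f"{g}.1" for g in planted["ratio_block"]])
    rcols = np.where(classes == "low")[0]
    log2_mean[np.ix_(rrows, rcols)] += cfg.ratio_block_log2_shift

    counts = _nb_draw(2.0**log2_mean, cfg.nb_dispersion, rng)
    tpm = _tpm_from_counts(counts)
    iso = IsoformMatrix(
        pd.DataFrame(tpm, index=tx_index, columns=lines),
        gene_of_tx,
        counts=pd.DataFrame(counts, index=tx_index, columns=lines),
    )
    return iso, pd.Series(classes, index=lines, name="ratio_class"), list(planted["ratio_block"])
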