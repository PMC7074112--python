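"""Self-contained differential-expression stage.

Selection follows the fold-change/FDR rule the downstream analyses
consume: a gene is "up" when q < α and log2FC > fc_min, "down" when
q < α and log2FC < −fc_min (defaults α = 0.01, fc_min = 2).

Counts are normalized by median-of-ratios size factors; per-gene p-values
come, by default, from a moderated t-test (empirical-Bayes variance
shrinkage) on log2-transformed normalized counts, which keeps usable
resolution at the small group sizes of a cell-line panel.  ``test="wilcoxon"`` switches to the rank-sum test.
Externally computed tables (e.g. a DESeq2 export) can be ingested with
:func:`read_deg_table`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma as sps_digamma, polygamma as sps_polygamma

from .errors import FormatError
from .stats import bh_fdr, wilcoxon_ranksum

logger = logging.getLogger(__name__)

__all__ = ["size_factors", "differential_expression", "common_deg", "read_deg_table"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    For genes positive in every sample, factor_j is the median of
    count_gj / (geometric mean of gene g across samples).  When no gene
    is positive in all samples, total-count scaling is used instead
    (logged).
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        logmat = np.log(mat[all_pos])
        log_geo = logmat.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logmat - log_geo, axis=0))
    else:
        logger.warning("size_factors: no gene positive in all samples; total-count fallback")
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _inv_trigamma(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = sps_polygamma(1, y)
        dif = tri * (1 - tri / x) / sps_polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _moderated_t_log2(norm_a: np.ndarray, norm_b: np.ndarray, pc: float) -> np.ndarray:
    """Moderated t-test on log2 expression with empirical-Bayes variance
    shrinkage (pooled per-gene variances squeezed toward a common prior,
    the standard small-sample treatment for expression data)."""
    la = np.log2(norm_a + pc)
    lb = np.log2(norm_b + pc)
    n1, n2 = la.shape[1], lb.shape[1]
    d = n1 + n2 - 2
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * va + (n2 - 1) * vb) / d

    pos = s2 > 0
    if pos.sum() >= 3:
        z = np.log(s2[pos])
        e_z = z.mean()
        var_z = z.var(ddof=1)
        resid = var_z - sps_polygamma(1, d / 2.0)
        if resid > 1e-8:
            d0 = 2.0 * _inv_trigamma(resid)
            s0_sq = np.exp(e_z - sps_digamma(d / 2.0) + sps_digamma(d0 / 2.0)
                           - np.log(d0 / d))
        else:  # variances more concentrated than chi²(d): infinite prior df
            d0 = np.inf
            s0_sq = np.exp(e_z - sps_digamma(d / 2.0) + np.log(d / 2.0))
        s2_mod = (d0 * s0_sq + d * s2) / (d0 + d) if np.isfinite(d0) \
            else np.full_like(s2, s0_sq)
        df_mod = d + d0
    else:
        s2_mod, df_mod = s2, d

    diff = la.mean(axis=1) - lb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    if np.isfinite(df_mod):
        p = 2.0 * sps.t.sf(np.abs(t), df_mod)
    else:
        p = 2.0 * sps.norm.sf(np.abs(t))
    p = np.asarray(p, dtype=float)
    # zero variance everywhere and equal means: undefined → 1
    p[np.isnan(p)] = 1.0
    return p


def differential_expression(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.01,
    fc_min: float = 2.0,
    pseudocount: float = 1.0,
    test: Literal["ttest", "wilcoxon"] = "ttest",
) -> pd.DataFrame:
    """Two-group differential expression on raw counts (A over B).

    Returns one row per gene: ``log2fc``, ``pvalue``, ``qvalue`` and
    ``direction`` (up/down/ns by the α and fold-change thresholds).
    Genes all-zero in both groups are ``ns`` with p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    sub = counts[group_a + group_b]
    factors = size_factors(sub)
    norm = sub.div(factors, axis=1)
    na = norm[group_a].to_numpy(dtype=float)
    nb = norm[group_b].to_numpy(dtype=float)

    log2fc = np.log2(na.mean(axis=1) + pseudocount) - np.log2(nb.mean(axis=1) + pseudocount)
    all_zero = (na.sum(axis=1) == 0) & (nb.sum(axis=1) == 0)

    if test == "ttest":
        p = _moderated_t_log2(na, nb, pseudocount)
    else:
        p = np.array([
            wilcoxon_ranksum(na[i], nb[i]).pvalue for i in range(na.shape[0])
        ])
    p[all_zero] = 1.0
    q = bh_fdr(p)

    direction = np.where((q < alpha) & (log2fc > fc_min), "up",
                np.where((q < alpha) & (log2fc < -fc_min), "down", "ns"))
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": p, "qvalue": q, "direction": direction},
        index=counts.index.rename("gene"),
    )


def common_deg(*results: pd.DataFrame) -> dict[str, list[str]]:
    """Genes up (resp. down) in every supplied DEG table, in the gene
    order of the first table."""
    if not results:
        raise ValueError("need at least one DEG table")
    up = set(results[0].index[results[0]["direction"] == "up"])
    down = set(results[0].index[results[0]["direction"] == "down"])
    for res in results[1:]:
        up &= set(res.index[res["direction"] == "up"])
        down &= set(res.index[res["direction"] == "down"])
    first = results[0].index
    return {"up": [g for g in first if g in up], "down": [g for g in first if g in down]}


def read_deg_table(path: str | Path, alpha: float = 0.01, fc_min: float = 2.0) -> pd.DataFrame:
    """Ingest an externally computed DEG table (gene, log2FC, padj dialect).

    Recognizes common column spellings (log2FoldChange/log2fc/logFC,
    padj/qvalue/FDR, pvalue/p) and re-derives the direction calls under
    the supplied thresholds.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    gene_col = next((cols[k] for k in ("gene", "gene_id", "symbol") if k in cols), df.columns[0])
    fc_col = next((cols[k] for k in ("log2foldchange", "log2fc", "logfc") if k in cols), None)
    q_col = next((cols[k] for k in ("padj", "qvalue", "fdr", "q") if k in cols), None)
    if fc_col is None or q_col is None:
        raise FormatError(f"{path}: need a log2 fold-change and an adjusted-p column")
    p_col = next((cols[k] for k in ("pvalue", "p", "pval") if k in cols), q_col)
    out = pd.DataFrame(
        {
            "log2fc": pd.to_numeric(df[fc_col], errors="coerce").to_numpy(),
            "pvalue": pd.to_numeric(df[p_col], errors="coerce").to_numpy(),
            "qvalue": pd.to_numeric(df[q_col], errors="coerce").to_numpy(),
        },
        index=pd.Index(df[gene_col].astype(str), name="gene"),
    )
    out["direction"] = np.where((out["qvalue"] < alpha) & (out["log2fc"] > fc_min), "up",
                       np.where((out["qvalue"] < alpha) & (out["log2fc"] < -fc_min), "down", "ns"))
    return out
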