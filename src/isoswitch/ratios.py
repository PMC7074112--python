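"""NF-YAs/NF-YAl isoform ratios and sample partitioning.

The central statistic is the per-sample TPM ratio of the short over the
long NF-YA splice isoform.  Samples are boxed two ways:

* a three-way threshold partition — low (ratio < 1), intermediate
  (1 ≤ ratio ≤ 5), high (ratio > 5); the boundary values, which the
  threshold definition leaves open, are assigned to the intermediate
  class;
* a quartile partition of a ranked cohort — bottom quarter (long-isoform
  dominant), top quarter (short-isoform dominant), middle half — used for
  the survival stratification.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import IsoformMatrix

logger = logging.getLogger(__name__)

__all__ = ["compute_ratio", "tri_class", "quartile_stratify", "partition_samples",
           "QUARTILE_LABELS"]

#: cohort labels for the quartile partition: low-ratio quarter, middle half, high-ratio quarter
QUARTILE_LABELS = ("NF-YAl_high", "intermediate", "NF-YAs_high")

DEFAULT_SHORT = "NFYA-s"
DEFAULT_LONG = "NFYA-l"


def tri_class(ratio: Sequence[float] | pd.Series, low: float = 1.0, high: float = 5.0) -> pd.Series:
    """Threshold partition of ratios into low / intermediate / high."""
    r = pd.Series(ratio, dtype=float)
    out = pd.Series("intermediate", index=r.index)
    out[r < low] = "low"
    out[r > high] = "high"
    return out


def compute_ratio(
    iso: IsoformMatrix,
    short_tx: str = DEFAULT_SHORT,
    long_tx: str = DEFAULT_LONG,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-sample short/long isoform TPM ratio with its threshold class.

    ratio = (TPM_short + pseudocount) / (TPM_long + pseudocount); the
    pseudocount (default 0.01 TPM) keeps zero denominators finite.

    Returns a DataFrame indexed by sample with columns ``ratio`` and
    ``tri_class``.
    """
    for tx in (short_tx, long_tx):
        if tx not in iso.tpm.index:
            raise KeyError(f"transcript {tx!r} not in matrix")
    s = iso.tpm.loc[short_tx].astype(float)
    l = iso.tpm.loc[long_tx].astype(float)
    ratio = (s + pseudocount) / (l + pseudocount)
    return pd.DataFrame({"ratio": ratio, "tri_class": tri_class(ratio)})


def quartile_stratify(ratios: pd.Series | Sequence[float],
                      labels: tuple[str, str, str] = QUARTILE_LABELS) -> pd.Series:
    """Quartile cohorts of a ranked ratio vector.

    The bottom floor(n/4) samples get ``labels[0]``, the top floor(n/4)
    get ``labels[2]``, the rest ``labels[1]``.  Boundary ties are broken
    by stable input order (logged); a constant vector degenerates to
    all-intermediate with a warning.
    """
    r = pd.Series(ratios, dtype=float)
    n = len(r)
    if n < 4:
        raise ValueError(f"need at least 4 samples to form quartiles, got {n}")
    out = pd.Series(labels[1], index=r.index)
    if r.nunique() == 1:
        logger.warning("quartile_stratify: all ratios equal; every sample is %s", labels[1])
        return out
    k = n // 4
    order = np.argsort(r.to_numpy(), kind="stable")
    if r.iloc[order[k - 1]] == r.iloc[order[k]] or r.iloc[order[-k]] == r.iloc[order[-k - 1]]:
        logger.info("quartile_stratify: ties at a quartile boundary broken by stable order")
    out.iloc[order[:k]] = labels[0]
    out.iloc[order[-k:]] = labels[2]
    return out


def partition_samples(
    iso: IsoformMatrix,
    short_tx: str = DEFAULT_SHORT,
    long_tx: str = DEFAULT_LONG,
    pseudocount: float = 0.01,
    quartiles: bool = True,
) -> pd.DataFrame:
    """Ratio, threshold class and (optionally) quartile cohort per sample."""
    part = compute_ratio(iso, short_tx, long_tx, pseudocount)
    if quartiles and len(part) >= 4:
        part["quartile_cohort"] = quartile_stratify(part["ratio"])
    else:
        part["quartile_cohort"] = "unknown"
    return part
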