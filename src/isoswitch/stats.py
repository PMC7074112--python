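"""Rank-based tests and multiplicity correction.

The comparisons the pipeline runs are two-group Wilcoxon rank-sum tests
(tumor vs. normal, low- vs. high-ratio), a Jonckheere–Terpstra trend test
for ordered groups (the three CpG-island methylator phenotype classes),
and Benjamini–Hochberg FDR control across genes or motif libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["RankSumResult", "JonckheereResult", "wilcoxon_ranksum", "jonckheere_trend", "bh_fdr"]

#: product of group sizes below which the exact null distribution is used
EXACT_LIMIT = 400


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  #: Mann–Whitney U of the first sample
    z: float  #: standardized statistic (tie-corrected variance, continuity corrected)
    pvalue: float
    method: str

    def __iter__(self):
        return iter((self.statistic, self.z, self.pvalue))


@dataclass(frozen=True)
class JonckheereResult:
    statistic: float  #: J = number of concordant between-group pairs (+ half-ties)
    z: float
    p_one_sided: float  #: upper tail: trend increasing with group order
    p_two_sided: float
    method: str

    def __iter__(self):
        return iter((self.statistic, self.z, self.p_one_sided))


def _tie_corrected_sd(pooled: np.ndarray, nx: int, ny: int) -> float:
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    return float(np.sqrt(var))


def wilcoxon_ranksum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    method: Literal["auto", "exact", "asymptotic"] = "auto",
) -> RankSumResult:
    """Unpaired two-sample Wilcoxon rank-sum (Mann–Whitney) test.

    The exact null distribution is used when ``n_x * n_y <= 400`` and the
    pooled sample is tie-free; otherwise the normal approximation with
    midrank ties, tie-corrected variance and continuity correction.
    Identical multisets give ``p = 1`` exactly.

    Returns
    -------
    RankSumResult with the U statistic of ``x``, the standardized z, and
    the p-value for ``alternative``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])

    mu = nx * ny / 2.0
    sd = _tie_corrected_sd(pooled, nx, ny)
    res_u = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    u = float(res_u.statistic)
    if sd == 0:  # all pooled values identical
        return RankSumResult(u, 0.0, 1.0, "degenerate")
    # continuity-corrected z for reporting
    z = (u - mu - 0.5 * np.sign(u - mu)) / sd

    if nx == ny and np.array_equal(np.sort(x), np.sort(y)):
        return RankSumResult(u, float(z), 1.0, "identical")

    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (nx * ny <= EXACT_LIMIT and not has_ties) else "asymptotic"
    if method == "exact" and has_ties:
        method = "asymptotic"

    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return RankSumResult(u, float(z), float(min(res.pvalue, 1.0)), method)


def _j_statistic(values: np.ndarray, group_idx: np.ndarray, k: int) -> float:
    """J = sum over ordered group pairs i<j of #{a < b} + 0.5 #{a == b}."""
    j = 0.0
    groups = [values[group_idx == i] for i in range(k)]
    for i in range(k - 1):
        gi = groups[i][:, None]
        for jdx in range(i + 1, k):
            gj = groups[jdx][None, :]
            j += (gi < gj).sum() + 0.5 * (gi == gj).sum()
    return float(j)


def jonckheere_trend(
    groups: Sequence[Sequence[float]],
    method: Literal["auto", "normal", "permutation"] = "auto",
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = 0,
) -> JonckheereResult:
    """Jonckheere–Terpstra test for an ordered alternative across k groups.

    ``groups`` are given in the hypothesized increasing order.  The null
    moments are the classical no-ties forms

        E[J]   = (N^2 - sum n_i^2) / 4
        Var[J] = [N^2 (2N+3) - sum n_i^2 (2 n_i + 3)] / 72

    With ``method="auto"`` the normal approximation is used on tie-free
    data and a seeded permutation null (``n_perm`` resamples) when ties
    are present.  The one-sided p is the upper tail (increasing trend).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least two ordered groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("all groups must be non-empty")

    sizes = np.array([a.size for a in arrs])
    n = int(sizes.sum())
    values = np.concatenate(arrs)
    group_idx = np.repeat(np.arange(k), sizes)

    j = _j_statistic(values, group_idx, k)
    mean = (n**2 - (sizes**2).sum()) / 4.0
    var = (n**2 * (2 * n + 3) - (sizes**2 * (2 * sizes + 3)).sum()) / 72.0
    z = (j - mean) / np.sqrt(var) if var > 0 else 0.0

    has_ties = np.unique(values).size < values.size
    if method == "auto":
        method = "permutation" if has_ties else "normal"

    if method == "normal":
        p_one = float(sps.norm.sf(z))
        p_two = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        ge = le = 0
        for _ in range(n_perm):
            perm = rng.permutation(values)
            jp = _j_statistic(perm, group_idx, k)
            ge += jp >= j
            le += jp <= j
        p_one = (1 + ge) / (n_perm + 1)
        p_lower = (1 + le) / (n_perm + 1)
        p_two = float(min(1.0, 2 * min(p_one, p_lower)))
    return JonckheereResult(j, float(z), float(p_one), p_two, method)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement.

    NaN entries propagate as NaN and take no part in the ranking.
    """
    p = np.asarray(pvalues, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if valid.sum():
        _, q_valid, _, _ = multipletests(p[valid], method="fdr_bh")
        q[valid] = q_valid
    return q
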