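"""Progression-free-interval analysis stratified by isoform-ratio cohort.

Kaplan–Meier product-limit curves per cohort, the multi-group log-rank
test, and Cox proportional-hazards regression with Efron tie handling
(PFI times come at day granularity, so ties are common).  Categorical
covariates are dummy-coded against explicitly declared reference levels —
in the reference analysis, the intermediate-ratio cohort; the reference
level is a mandatory argument, never defaulted silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergence
from lifelines.statistics import multivariate_logrank_test

from .errors import ConvergenceError

logger = logging.getLogger(__name__)

__all__ = ["SurvivalFit", "CoxFit", "km_estimate", "logrank", "cox_fit"]


@dataclass
class SurvivalFit:
    """Per-group Kaplan–Meier step functions."""

    tables: dict[str, pd.DataFrame]  #: group → (time, at_risk, events, survival, se)

    def survival_at(self, group: str, t: float) -> float:
        """S(t) for a group: the step-function value at time t."""
        tab = self.tables[group]
        prior = tab[tab["time"] <= t]
        return float(prior["survival"].iloc[-1]) if len(prior) else 1.0

    @property
    def groups(self) -> list[str]:
        return list(self.tables)


@dataclass
class CoxFit:
    """Cox PH estimates: one row per dummy-coded covariate level."""

    summary: pd.DataFrame  #: beta, hr, se, z, pvalue, ci_low, ci_high
    references: dict[str, str]
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _check_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be finite and ≥ 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events, groups=None) -> SurvivalFit:
    """Kaplan–Meier product-limit estimate per group (Greenwood SE).

    Empty groups are skipped with a warning; with ``groups=None`` a single
    curve named ``"all"`` is fitted.
    """
    t, e = _check_times(times, events)
    g = pd.Series(["all"] * len(t)) if groups is None else pd.Series(list(groups))
    tables: dict[str, pd.DataFrame] = {}
    for name in g.unique():
        mask = (g == name).to_numpy()
        if mask.sum() == 0:
            logger.warning("km_estimate: empty group %r skipped", name)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        ev = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0].reindex(ev.index).to_numpy(dtype=float)
        n_at_risk = ev["at_risk"].to_numpy(dtype=float)
        d = ev["observed"].to_numpy(dtype=float)
        # Greenwood: Var S(t) = S(t)^2 * cumsum d / (n (n - d))
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.nan)
        se = surv * np.sqrt(np.cumsum(np.nan_to_num(term)))
        tab = pd.DataFrame({
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": n_at_risk,
            "events": d,
            "survival": surv,
            "se": se,
        })
        tables[str(name)] = tab.reset_index(drop=True)
    if not tables:
        raise ValueError("no non-empty groups")
    return SurvivalFit(tables)


def logrank(times, events, groups) -> tuple[float, int, float]:
    """Multi-group log-rank test → (chi-square, df, p).

    With no events at all the test is vacuous and returns p = 1.
    """
    t, e = _check_times(times, events)
    g = pd.Series(list(groups))
    names = [n for n in g.unique() if (g == n).any()]
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups")
    df = len(names) - 1
    if e.sum() == 0:
        return 0.0, df, 1.0
    res = multivariate_logrank_test(t, g.to_numpy(), e)
    return float(res.test_statistic), df, float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    categorical: dict[str, str] | None = None,
    numeric: list[str] | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit with Efron ties.

    ``categorical`` maps each categorical covariate to its reference
    level (e.g. ``{"cohort": "intermediate", "subtype": "PI", "stage": "I"}``);
    every non-reference level becomes a dummy named ``<col>=<level>``.
    ``numeric`` columns enter as-is.  Raises :class:`ConvergenceError` on
    non-convergence, separation or collinear dummies.
    """
    categorical = categorical or {}
    numeric = list(numeric or [])
    cols = [duration_col, event_col, *categorical, *numeric]
    sub = data[cols].dropna()
    n_drop = len(data) - len(sub)
    if n_drop:
        logger.info("cox_fit: excluded %d records with missing fields", n_drop)
    t, e = _check_times(sub[duration_col], sub[event_col])
    if e.sum() < 1:
        raise ValueError("need at least one event")

    design = pd.DataFrame({duration_col: t, event_col: e}, index=sub.index)
    for col, ref in categorical.items():
        levels = pd.Series(sub[col]).astype(str)
        if ref not in set(levels):
            raise ValueError(f"reference level {ref!r} absent from {col!r}")
        for lev in sorted(set(levels) - {ref}):
            design[f"{col}={lev}"] = (levels == lev).astype(float)
    for col in numeric:
        design[col] = pd.to_numeric(sub[col])

    x = design.drop(columns=[duration_col, event_col])
    if x.shape[1] == 0:
        raise ValueError("no covariates")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x.to_numpy()]))
    if rank < x.shape[1] + 1:
        raise ConvergenceError("collinear covariate dummies")

    cph = CoxPHFitter()  # Efron partial likelihood is the lifelines default
    try:
        cph.fit(design, duration_col=duration_col, event_col=event_col)
    except (_LLConvergence, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc

    s = cph.summary
    summary = pd.DataFrame({
        "beta": s["coef"],
        "hr": s["exp(coef)"],
        "se": s["se(coef)"],
        "z": s["z"],
        "pvalue": s["p"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
    })
    summary.index.name = "covariate"
    return CoxFit(summary, references=dict(categorical), n=len(sub), n_events=int(e.sum()))
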