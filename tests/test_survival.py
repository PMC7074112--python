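"""Kaplan–Meier, log-rank and Cox PH against hand and grid oracles."""

import numpy as np
import pandas as pd
import pytest

from isoswitch import cox_fit, km_estimate, logrank
from isoswitch.errors import ConvergenceError


def efron_partial_loglik(beta, times, events, x):
    """Hand-coded Efron partial log-likelihood for one covariate."""
    ll = 0.0
    eta = beta * np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    for t in np.unique(times[events == 1]):
        risk = times >= t
        tied = (times == t) & (events == 1)
        d = tied.sum()
        sum_risk = np.exp(eta[risk]).sum()
        sum_tied = np.exp(eta[tied]).sum()
        ll += eta[tied].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_tied)
    return ll


class TestKaplanMeier:
    def test_no_censoring_reduces_to_empirical_fraction(self, rng):
        times = rng.exponential(10, 40)
        fit = km_estimate(times, np.ones(40))
        tab = fit.tables["all"]
        surviving = [(times > t).mean() for t in tab["time"]]
        np.testing.assert_allclose(tab["survival"], surviving, atol=1e-12)

    def test_all_censored_is_flat_one(self):
        fit = km_estimate([1, 2, 3, 4], [0, 0, 0, 0])
        assert fit.survival_at("all", 4) == 1.0

    def test_six_subject_worked_fixture(self):
        # times 1, 2+, 3, 4, 5+, 6 → S(3) = (5/6)(3/4) = 0.625
        fit = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        assert fit.survival_at("all", 3) == pytest.approx(0.625)

    def test_time_unit_invariance(self, rng):
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        f1 = km_estimate(times, events)
        f2 = km_estimate(times * 365.0, events)
        np.testing.assert_allclose(f1.tables["all"]["survival"],
                                   f2.tables["all"]["survival"])


class TestLogrank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 5] * 2
        events = [1, 1, 0, 1, 1] * 2
        groups = ["a"] * 5 + ["b"] * 5
        chi2, df, p = logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_no_events_is_vacuous(self):
        chi2, df, p = logrank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert p == 1.0

    def test_matches_permutation_oracle(self, rng):
        n = 20
        times = np.round(rng.exponential(10, n), 1)
        events = rng.integers(0, 2, n)
        events[:4] = 1  # ensure events exist
        groups = np.array(["a"] * 10 + ["b"] * 10)
        chi2, _, p = logrank(times, events, groups)

        def chi2_of(g):
            return logrank(times, events, g)[0]

        perm_stats = np.array([chi2_of(rng.permutation(groups)) for _ in range(2000)])
        p_perm = (1 + (perm_stats >= chi2).sum()) / 2001
        assert p == pytest.approx(p_perm, abs=0.03)


class TestCox:
    def test_null_single_covariate_calibration(self):
        # binary covariate with no true effect: |beta| < 2 SE in ≥ 94% of sims
        rng = np.random.default_rng(0)
        ok = 0
        reps = 300
        for _ in range(reps):
            n = 60
            df = pd.DataFrame({
                "time": np.ceil(rng.exponential(100, n)),
                "event": rng.random(n) < 0.8,
                "x": rng.integers(0, 2, n).astype(float),
            })
            df["event"] = df["event"].astype(int)
            fit = cox_fit(df, "time", "event", numeric=["x"])
            ok += abs(fit.summary.loc["x", "beta"]) < 2 * fit.summary.loc["x", "se"]
        assert ok / reps >= 0.94

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        n = 15
        x = rng.integers(0, 2, n).astype(float)
        times = np.ceil(rng.exponential(30 / (1 + x), n))  # true beta = log 2-ish
        events = (rng.random(n) < 0.85).astype(int)
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        fit = cox_fit(df, "time", "event", numeric=["x"])

        grid = np.arange(-4, 4, 1e-4)
        ll = np.array([efron_partial_loglik(b, times, events, x) for b in grid[::100]])
        coarse = grid[::100][np.argmax(ll)]
        fine = np.arange(coarse - 0.02, coarse + 0.02, 1e-4)
        beta_star = fine[np.argmax([efron_partial_loglik(b, times, events, x)
                                    for b in fine])]
        assert fit.summary.loc["x", "beta"] == pytest.approx(beta_star, abs=1e-3)

    def test_reference_levels_and_dummies(self):
        rng = np.random.default_rng(3)
        n = 120
        cohort = rng.choice(["low", "mid", "high"], n)
        df = pd.DataFrame({
            "time": np.ceil(rng.exponential(50, n)),
            "event": (rng.random(n) < 0.7).astype(int),
            "cohort": cohort,
        })
        fit = cox_fit(df, "time", "event", categorical={"cohort": "mid"})
        assert set(fit.summary.index) == {"cohort=high", "cohort=low"}
        assert fit.references == {"cohort": "mid"}
        assert (fit.summary["hr"] > 0).all()
        assert ((fit.summary["ci_low"] <= fit.summary["hr"])
                & (fit.summary["hr"] <= fit.summary["ci_high"])).all()

    def test_missing_reference_level_rejected(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 1, 0],
                           "g": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError):
            cox_fit(df, "time", "event", categorical={"g": "zzz"})

    def test_collinear_dummies_rejected(self):
        df = pd.DataFrame({
            "time": [1.0, 2, 3, 4, 5, 6], "event": [1, 1, 0, 1, 1, 0],
            "x": [0.0, 0, 0, 1, 1, 1], "y": [0.0, 0, 0, 2, 2, 2],
        })
        with pytest.raises(ConvergenceError):
            cox_fit(df, "time", "event", numeric=["x", "y"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0], "x": [1.0, 0, 1]})
        with pytest.raises(ValueError):
            cox_fit(df, "time", "event", numeric=["x"])
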