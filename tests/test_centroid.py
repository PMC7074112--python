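"""Median-centered nearest-centroid classification and signature filtering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from isoswitch import (
    CentroidSet,
    MedianCentroidClassifier,
    SignatureRatioClassifier,
    build_centroid,
    classify,
    collapse_to_gene,
    filter_uninformative,
    median_center,
    two_class_from_signature,
)


class TestMedianCenter:
    def test_worked_example(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        np.testing.assert_allclose(median_center(m).to_numpy(), [[-1, 0, 1]])

    def test_constant_row_is_zeroed(self):
        m = pd.DataFrame([[5.0] * 4], index=["g"])
        assert (median_center(m) == 0).all().all()

    def test_every_row_has_zero_median(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 9)))
        np.testing.assert_allclose(median_center(m).median(axis=1), 0, atol=1e-12)


class TestBuildCentroid:
    def test_identical_pairs_give_their_centered_values(self):
        m = pd.DataFrame({"a1": [1.0, 4], "a2": [1.0, 4], "b1": [3.0, 0], "b2": [3.0, 0]},
                         index=["g1", "g2"])
        cs = build_centroid(m, pd.Series(["A", "A", "B", "B"], index=m.columns))
        centered = median_center(m)
        np.testing.assert_allclose(cs.profile["A"], centered[["a1", "a2"]].mean(axis=1))

    def test_sample_order_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(15, 8)), columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["A", "B"] * 4, index=m.columns)
        p1 = build_centroid(m, labels).profile
        perm = list(rng.permutation(m.columns))
        p2 = build_centroid(m[perm], labels[perm]).profile
        pd.testing.assert_frame_equal(p1, p2)

    def test_small_class_refused(self):
        m = pd.DataFrame(np.ones((3, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            build_centroid(m, pd.Series(["A", "A", "B"], index=m.columns))

    def test_recovers_generating_shifts(self, cohort):
        iso, meta, truth = cohort
        tumors = truth["samples"].index
        expr = np.log2(collapse_to_gene(iso).values[tumors] + 1)
        cs = build_centroid(expr, truth["samples"]["subtype"])
        # oracle: build the same centroid from the noiseless generator means
        nb_gene = truth["nb_mean"][tumors].groupby(
            iso.gene_of_transcript.loc[truth["nb_mean"].index]).sum()
        expected = build_centroid(np.log2(nb_gene + 1),
                                  truth["samples"]["subtype"]).profile
        # compare the class-discriminating contrast (skewed count noise adds a
        # class-independent mean-vs-median offset that carries no information)
        obs_c = cs.profile.sub(cs.profile.mean(axis=1), axis=0)
        exp_c = expected.sub(expected.mean(axis=1), axis=0).loc[obs_c.index]
        for st in truth["subtype_blocks"]:
            r = np.corrcoef(obs_c[st], exp_c[st])[0, 1]
            assert r > 0.9


class TestClassify:
    def _profiles(self):
        return CentroidSet(pd.DataFrame(
            {"A": [2.0, -1, -1, 0], "B": [-1.0, 2, -1, 0.5]},
            index=[f"g{i}" for i in range(4)]))

    def test_exact_profile_match_scores_unity(self):
        cs = self._profiles()
        # two samples so cohort medians do not erase the signal
        m = pd.DataFrame({"s1": cs.profile["A"], "s2": -cs.profile["A"]})
        res = classify(m, cs)
        assert res.loc["s1", "class"] == "A"
        assert res.loc["s1", "r_A"] == pytest.approx(1.0)

    def test_anticorrelated_sample_gets_other_class(self):
        prof = CentroidSet(pd.DataFrame({"A": [1.0, -1, 1, -1], "B": [-1.0, 1, -1, 1]},
                                        index=[f"g{i}" for i in range(4)]))
        m = pd.DataFrame({"s1": [-1.0, 1, -1, 1], "s2": [1.0, -1, 1, -1]},
                         index=prof.profile.index)
        res = classify(m, prof)
        assert res.loc["s1", "class"] == "B"

    def test_flat_sample_is_unknown(self):
        cs = self._profiles()
        m = pd.DataFrame({"s1": [1.0, 2, 3, 4], "s2": [2.0, 2, 2, 2]},
                         index=cs.profile.index)
        res = classify(m, cs)
        assert res.loc["s2", "class"] == "unknown"

    def test_margins_non_negative(self, cohort):
        iso, meta, truth = cohort
        tumors = truth["samples"].index
        expr = np.log2(collapse_to_gene(iso).values[tumors] + 1)
        cs = build_centroid(expr, truth["samples"]["subtype"])
        res = classify(expr, cs)
        assert (res["margin"].dropna() >= 0).all()

    def test_invariance_global_scale_and_gene_offsets(self, rng):
        genes = [f"g{i}" for i in range(10)]
        m = pd.DataFrame(rng.normal(size=(10, 12)), index=genes)
        cs = CentroidSet(pd.DataFrame(rng.normal(size=(10, 3)), index=genes,
                                      columns=list("ABC")))
        base = classify(m, cs)["class"]
        # common positive rescaling of both matrix and centroids
        scaled = classify(3.7 * m, CentroidSet(3.7 * cs.profile))["class"]
        pd.testing.assert_series_equal(base, scaled)
        # per-gene offsets on the matrix are absorbed by median centering
        offs = pd.Series(rng.normal(size=10) * 5, index=genes)
        shifted = classify(m.add(offs, axis=0), cs)["class"]
        pd.testing.assert_series_equal(base, shifted)

    def test_too_few_shared_genes_refused(self):
        cs = self._profiles()
        m = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g0"])
        with pytest.raises(ValueError):
            classify(m, cs)


class TestTwoClassSignature:
    def test_up_gene_overexpression_is_low_ratio_like(self, rng):
        genes = [f"g{i}" for i in range(20)]
        m = pd.DataFrame(rng.normal(0, 0.1, size=(20, 10)), index=genes)
        m.loc[genes[:5], m.columns[:3]] += 4.0  # tumors overexpressing the up set
        res = two_class_from_signature(m, up_genes=genes[:5], down_genes=genes[5:10])
        assert (res["class"].iloc[:3] == "low_ratio_like").all()

    def test_up_only_signature_uses_score(self, rng):
        genes = [f"g{i}" for i in range(10)]
        m = pd.DataFrame(rng.normal(0, 0.1, size=(10, 8)), index=genes)
        m.loc[genes[:4], m.columns[:2]] += 3.0
        res = two_class_from_signature(m, up_genes=genes[:4])
        assert "score" in res.columns
        assert (res["class"].iloc[:2] == "low_ratio_like").all()
        assert (res["class"].iloc[2:] == "high_ratio_like").all()

    def test_flat_sample_unknown(self):
        genes = [f"g{i}" for i in range(4)]
        m = pd.DataFrame({"s1": [1.0, 2, 3, 4], "s2": [1.0, 1, 1, 1]}, index=genes)
        res = two_class_from_signature(m, up_genes=genes)
        assert res.loc["s2", "class"] == "unknown"

    def test_tiny_signature_refused(self):
        m = pd.DataFrame(np.ones((3, 3)), index=list("abc"))
        with pytest.raises(ValueError):
            two_class_from_signature(m, up_genes=["a"])


class TestFilterUninformative:
    def _fixture(self, rng):
        genes = ["same", "sep", "weak"]
        cols = [f"s{i}" for i in range(8)]
        m = pd.DataFrame(rng.normal(8, 0.01, size=(3, 8)), index=genes, columns=cols)
        m.loc["same"] = 8.0  # exactly equal group medians
        labels = pd.Series(["low"] * 4 + ["high"] * 4, index=cols)
        m.loc["sep", labels == "low"] = m.loc["sep", labels == "low"] * 8  # ≈3 log2
        m.loc["weak", labels == "low"] *= 1.2
        return m, labels

    def test_identical_medians_dropped(self, rng):
        m, labels = self._fixture(rng)
        retained, deltas = filter_uninformative(m, ["same"], labels, delta=1e-6)
        assert retained == []

    def test_planted_separation_retained(self, rng):
        m, labels = self._fixture(rng)
        retained, deltas = filter_uninformative(m, ["same", "sep", "weak"], labels, delta=1.0)
        assert retained == ["sep"]
        assert deltas["sep"] == pytest.approx(3.0, abs=0.2)

    def test_zero_delta_retains_all(self, rng):
        m, labels = self._fixture(rng)
        retained, _ = filter_uninformative(m, ["same", "sep", "weak"], labels, delta=0.0)
        assert retained == ["same", "sep", "weak"]


class TestSklearnEstimators:
    def test_fit_predict_recovers_labels(self, rng):
        X = rng.normal(size=(30, 12))
        y = np.array(["A", "B", "C"] * 10)
        for cls, shift in zip("ABC", range(3)):
            X[y == cls, shift * 4:(shift + 1) * 4] += 3.0
        clf = MedianCentroidClassifier().fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9
        assert clf.decision_function(X).shape == (30, 3)
        assert list(clf.classes_) == ["A", "B", "C"]

    def test_clone_and_params_roundtrip(self):
        clf = MedianCentroidClassifier(feature_names=["a", "b", "c"])
        params = clf.get_params()
        assert params["feature_names"] == ["a", "b", "c"]
        clone(clf)  # sklearn-compatible construction

    def test_signature_estimator(self, rng):
        genes = [f"g{i}" for i in range(12)]
        X = rng.normal(0, 0.1, size=(6, 12))
        X[:2, :4] += 3.0
        clf = SignatureRatioClassifier(up_genes=genes[:4], down_genes=genes[4:8],
                                       feature_names=genes).fit()
        pred = clf.predict(X)
        assert (pred[:2] == "low_ratio_like").all()
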