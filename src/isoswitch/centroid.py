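"""Median-centered Pearson nearest-centroid classification.

Each gene is median-centered across the cohort being classified; a sample
is assigned to the class whose reference profile it correlates with best.
The same machinery serves two jobs: extending molecular-subtype labels
from a labeled subset to a whole cohort, and predicting a sample's
isoform-ratio class from a cell-line-derived gene signature (±1 profiles
over the up/down signature genes).

Exposed both as functions mirroring the procedure's steps and as
scikit-learn estimators (:class:`MedianCentroidClassifier`,
:class:`SignatureRatioClassifier`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidSet",
    "median_center",
    "build_centroid",
    "classify",
    "two_class_from_signature",
    "filter_uninformative",
    "MedianCentroidClassifier",
    "SignatureRatioClassifier",
]


@dataclass
class CentroidSet:
    """Gene × class reference profiles (median-centered expression)."""

    profile: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profile.shape[0] < 2:
            raise ValueError("centroid set needs at least 2 genes")
        if self.profile.shape[1] < 1:
            raise ValueError("centroid set needs at least 1 class")
        if self.profile.index.duplicated().any():
            raise ValueError("duplicate genes in centroid set")

    @property
    def genes(self) -> list[str]:
        return list(self.profile.index)

    @property
    def classes(self) -> list[str]:
        return list(self.profile.columns)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's median across samples (rows = genes)."""
    if matrix.shape[1] < 1:
        raise ValueError("need at least one sample")
    return matrix.sub(matrix.median(axis=1), axis=0)


def build_centroid(matrix: pd.DataFrame, labels: pd.Series | Sequence[str]) -> CentroidSet:
    """Class centroids from labeled samples: per class, the mean of the
    median-centered expression. Every class needs ≥ 2 samples."""
    labels = pd.Series(labels, index=matrix.columns) if not isinstance(labels, pd.Series) \
        else labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a label")
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"classes with < 2 samples: {list(small.index)}")
    centered = median_center(matrix)
    profile = centered.T.groupby(labels).mean().T
    return CentroidSet(profile.sort_index(axis=1))


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations: x (g×n) vs y (g×k) → n×k."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xs = np.sqrt((xc**2).sum(axis=0))
    ys = np.sqrt((yc**2).sum(axis=0))
    num = xc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.outer(xs, ys)
    return r


def classify(matrix: pd.DataFrame, centroids: CentroidSet) -> pd.DataFrame:
    """Assign each sample (column) to its best-correlated class profile.

    The matrix is restricted to genes shared with the centroid set and
    median-centered on its own cohort.  Returns one row per sample:
    ``class``, ``margin`` (best r − runner-up r), ``tied`` flag, and a
    correlation column ``r_<class>`` per class.  Samples with zero
    variance over the shared genes get class ``unknown``.
    """
    shared = matrix.index.intersection(centroids.profile.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} genes shared with the centroid set")
    logger.info("classify: %d/%d centroid genes present", len(shared), len(centroids.genes))
    raw = matrix.loc[shared]
    sub = median_center(raw)
    prof = centroids.profile.loc[shared]
    r = _pearson_matrix(sub.to_numpy(dtype=float), prof.to_numpy(dtype=float))

    classes = np.array(centroids.classes)
    out = pd.DataFrame(r, index=matrix.columns, columns=[f"r_{c}" for c in classes])
    # a sample flat over the shared genes carries no profile information
    valid = ~np.isnan(r).all(axis=1) & (raw.nunique(axis=0) > 1).to_numpy()
    best = np.zeros(len(out), dtype=int)
    margin = np.full(len(out), np.nan)
    tied = np.zeros(len(out), dtype=bool)
    rv = np.where(np.isnan(r), -np.inf, r)
    best = rv.argmax(axis=1)
    if r.shape[1] > 1:
        part = np.sort(rv, axis=1)
        with np.errstate(invalid="ignore"):
            margin = part[:, -1] - part[:, -2]
        tied = margin == 0
    else:
        margin = np.zeros(len(out))
    out["class"] = np.where(valid, classes[best], "unknown")
    out["margin"] = np.where(valid, margin, np.nan)
    out["tied"] = tied & valid
    if (~valid).any():
        logger.warning("classify: %d samples with zero variance → unknown", (~valid).sum())
    if out["tied"].any():
        logger.warning("classify: %d tied assignments (margin 0)", int(out["tied"].sum()))
    return out


def two_class_from_signature(
    matrix: pd.DataFrame,
    up_genes: Sequence[str],
    down_genes: Sequence[str] | None = None,
    labels: tuple[str, str] = ("low_ratio_like", "high_ratio_like"),
) -> pd.DataFrame:
    """Two-class prediction from a gene signature.

    Builds a ±1 centroid pair — +1 on ``up_genes`` / −1 on ``down_genes``
    and its negation — and classifies.  A sample positively correlated
    with the up-signature is called ``low_ratio_like`` (the signature is
    derived from low-ratio lines).

    With a one-sided signature (only up or only down genes) the ±1
    profile is constant over the signature genes and Pearson correlation
    is undefined; the sample's mean median-centered expression over the
    signature then serves as the score (positive mean over up-genes →
    ``low_ratio_like``), reported in a ``score`` column with
    ``margin = |score|``.  A flat sample is ``unknown``.
    """
    up = [g for g in up_genes if g in matrix.index]
    down = [g for g in (down_genes or []) if g in matrix.index]
    if len(up) + len(down) < 2:
        raise ValueError("signature too small after restricting to measured genes")
    if up and down:
        sig = pd.Series(1.0, index=pd.Index(up + down, name="gene"))
        sig.loc[down] = -1.0
        profile = pd.DataFrame({labels[0]: sig, labels[1]: -sig})
        return classify(matrix, CentroidSet(profile))

    sig_genes = up or down
    sign = 1.0 if up else -1.0
    centered = median_center(matrix.loc[sig_genes])
    score = sign * centered.mean(axis=0)
    flat = matrix.loc[sig_genes].nunique(axis=0) <= 1
    out = pd.DataFrame(index=matrix.columns)
    out["score"] = score
    out["class"] = np.where(flat, "unknown", np.where(score > 0, labels[0], labels[1]))
    out["margin"] = np.where(flat, np.nan, score.abs())
    out["tied"] = (score == 0) & ~flat
    return out


def filter_uninformative(
    matrix: pd.DataFrame,
    genes: Sequence[str],
    labels: pd.Series,
    delta: float = 1.0,
    log2_transform: bool = True,
) -> tuple[list[str], pd.Series]:
    """Drop signature genes with similar group medians.

    For each gene, the absolute difference of the two group medians (on
    log2(x+1) expression unless ``log2_transform=False``) is compared to
    ``delta``; genes with difference < delta are discarded.  Returns the
    retained gene list and the per-gene deltas.
    """
    labels = labels.reindex(matrix.columns).dropna()
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    present = [g for g in genes if g in matrix.index]
    sub = matrix.loc[present, labels.index]
    if log2_transform:
        sub = np.log2(sub + 1.0)
    med_a = sub[labels.index[labels == groups[0]]].median(axis=1)
    med_b = sub[labels.index[labels == groups[1]]].median(axis=1)
    deltas = (med_a - med_b).abs()
    retained = [g for g in present if deltas[g] >= delta]
    logger.info("filter_uninformative: retained %d/%d genes at δ=%g",
                len(retained), len(present), delta)
    return retained, deltas


class MedianCentroidClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid classifier with median centering and Pearson affinity.

    sklearn-style wrapper over :func:`build_centroid` / :func:`classify`:
    ``X`` is samples × genes.  Median centering is always recomputed on
    the cohort being classified, so predictions depend on the composition
    of ``X`` — by design, mirroring how the reference procedure centers
    on the full target cohort.

    Attributes
    ----------
    centroids_ : CentroidSet
        Gene × class reference profiles learned in ``fit``.
    classes_ : ndarray
        Sorted class labels.
    """

    def __init__(self, feature_names: Sequence[str] | None = None):
        self.feature_names = feature_names

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X, dtype=float)
        names = self.feature_names or [f"g{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X.T, index=list(names))

    def fit(self, X, y):
        mat = self._to_frame(X)
        self.n_features_in_ = mat.shape[0]
        self.centroids_ = build_centroid(mat, pd.Series(list(y), index=mat.columns))
        self.classes_ = np.array(self.centroids_.classes)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        return classify(self._to_frame(X), self.centroids_)["class"].to_numpy()

    def decision_function(self, X) -> np.ndarray:
        """Per-class Pearson correlations, samples × classes."""
        check_is_fitted(self, "centroids_")
        res = classify(self._to_frame(X), self.centroids_)
        return res[[f"r_{c}" for c in self.classes_]].to_numpy()


class SignatureRatioClassifier(ClassifierMixin, BaseEstimator):
    """Two-class ratio predictor from an up/down gene signature.

    ``fit`` only validates the signature (the profile is fixed ±1);
    ``predict`` runs :func:`two_class_from_signature` on samples × genes
    input with the gene names supplied at construction.
    """

    def __init__(self, up_genes: Sequence[str] = (), down_genes: Sequence[str] = (),
                 feature_names: Sequence[str] | None = None):
        self.up_genes = up_genes
        self.down_genes = down_genes
        self.feature_names = feature_names

    def fit(self, X=None, y=None):
        if len(list(self.up_genes)) + len(list(self.down_genes)) < 2:
            raise ValueError("signature needs at least 2 genes")
        self.classes_ = np.array(["high_ratio_like", "low_ratio_like"])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        if isinstance(X, pd.DataFrame):
            mat = X.T
        else:
            X = np.asarray(X, dtype=float)
            names = self.feature_names or [f"g{i}" for i in range(X.shape[1])]
            mat = pd.DataFrame(X.T, index=list(names))
        res = two_class_from_signature(mat, list(self.up_genes), list(self.down_genes))
        return res["class"].to_numpy()
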