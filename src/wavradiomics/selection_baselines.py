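"""Comparison feature selectors: variance/correlation filters, PCA, wrappers.

The variance filter operates on raw (pre-standardization) features — after
standardization every variance is 1 and a threshold would be meaningless.
The correlation filter is a deterministic greedy scan in column order:
when a pair exceeds the threshold, the later column is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression


@dataclass
class BaselineConfig:
    tau_v: float = 0.5          # variance threshold (raw features)
    tau_c: float = 0.99         # |Pearson r| threshold
    pca_retain: float = 0.99    # explained-variance fraction
    wrapper_k: int = 30

    def __post_init__(self) -> None:
        if self.tau_v < 0 or not (0 < self.tau_c <= 1) \
                or not (0 < self.pca_retain <= 1) or self.wrapper_k < 1:
            raise ValueError("invalid baseline configuration")


def variance_filter(X: np.ndarray, tau_v: float = 0.5) -> np.ndarray:
    """Indices of columns with raw variance strictly above ``tau_v``."""
    X = np.asarray(X, dtype=float)
    return np.where(X.var(axis=0) > tau_v)[0]


def correlation_filter(X: np.ndarray, tau_c: float = 0.99) -> np.ndarray:
    """Greedy redundancy removal: drop the later column of each pair with
    |Pearson r| > tau_c.  Zero-variance columns are dropped first."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        return np.arange(X.shape[1])
    variances = X.var(axis=0)
    candidates = np.where(variances > 0)[0]
    if candidates.size < X.shape[1]:
        warnings.warn("zero-variance columns dropped before correlation filter")
    if candidates.size == 0:
        return candidates
    corr = np.corrcoef(X[:, candidates], rowvar=False)
    corr = np.atleast_2d(corr)
    kept: list[int] = []
    for pos in range(candidates.size):
        if all(abs(corr[pos, kpos]) <= tau_c for kpos in kept):
            kept.append(pos)
    return candidates[kept]


@dataclass
class PCAReduction:
    """A fitted PCA basis retaining a target explained-variance fraction."""

    mean: np.ndarray
    components: np.ndarray       # (n_components, N)
    n_components: int
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


def pca_reduce(X: np.ndarray, retain: float = 0.99) -> PCAReduction:
    """Smallest component count whose cumulative explained variance covers
    ``retain`` of the total (input should be standardized)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, retain - 1e-12) + 1)
    k = min(k, len(cum))
    return PCAReduction(mean=pca.mean_, components=pca.components_[:k],
                        n_components=k,
                        explained_variance_ratio=pca.explained_variance_ratio_[:k])


def linear_model_ranker(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|coefficient| scores from an L2 logistic fit (wrapper contract)."""
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X, y)
    return np.abs(clf.coef_.ravel())


def random_forest_ranker(X: np.ndarray, y: np.ndarray, seed: int = 0,
                         n_estimators: int = 200) -> np.ndarray:
    """Impurity importances from a random forest (wrapper contract)."""
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X, y)
    return clf.feature_importances_


def wrapper_topk(X: np.ndarray, y: np.ndarray, ranker=linear_model_ranker,
                 k: int = 30) -> np.ndarray:
    """Indices of the k largest importance scores; ties break by column order."""
    X = np.asarray(X, dtype=float)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {X.shape[1]}")
    scores = np.asarray(ranker(X, y), dtype=float)
    if scores.size != X.shape[1]:
        raise ValueError("ranker must return one score per feature")
    return np.argsort(-scores, kind="stable")[:k]
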