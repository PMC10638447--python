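"""Metrics and statistical comparison machinery.

AUC uses the Mann-Whitney formulation (ties count one half).  Repeated
stratified cross-validation refits the entire pipeline — standardization,
feature selection, classifier — inside every training fold, so no
information leaks from held-out rows.  Confidence intervals: normal
approximation over CV replicates, percentile over bootstrap resamples.
AUC comparisons on a shared test set use DeLong's structural-components
test; comparisons of CV replicate distributions use Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold


class ProbabilisticClassifier(Protocol):
    """Contract for pipelines evaluated here."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ProbabilisticClassifier": ...
    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray: ...


@dataclass
class MetricSummary:
    point: float
    ci: tuple[float, float]
    replicates: np.ndarray

    def as_dict(self) -> dict:
        return {"point": self.point, "ci": list(self.ci),
                "n_replicates": int(self.replicates.size)}


@dataclass
class EvalReport:
    metrics: dict[str, MetricSummary]
    comparisons: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"metrics": {k: v.as_dict() for k, v in self.metrics.items()},
                "comparisons": self.comparisons, "config": self.config}


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score_+ > score_-) + 0.5 P(score_+ = score_-)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def f1(predicted: Sequence[int], labels: Sequence[int]) -> float:
    """Harmonic mean of precision and recall; 0 when undefined."""
    predicted = np.asarray(predicted, dtype=int)
    labels = np.asarray(labels, dtype=int)
    tp = int(((predicted == 1) & (labels == 1)).sum())
    fp = int(((predicted == 1) & (labels == 0)).sum())
    fn = int(((predicted == 0) & (labels == 1)).sum())
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2.0 * tp / denom


def _normal_ci(values: np.ndarray, rho: float = 0.0) -> tuple[float, float]:
    """Normal-approximation CI over replicates.

    ``rho`` is the Nadeau-Bengio dependence correction for cross-validation
    replicates (test/train size ratio, ``1/(folds-1)`` for k-fold): fold
    results share the dataset, so the naive ``se/sqrt(R)`` undercovers.
    """
    mean = float(values.mean())
    if values.size > 1:
        se = float(values.std(ddof=1) * np.sqrt(1.0 / values.size + rho))
    else:
        se = 0.0
    return (mean - 1.96 * se, mean + 1.96 * se)


def repeated_cv_evaluate(
    pipeline_factory: Callable[[], ProbabilisticClassifier],
    X: np.ndarray, y: np.ndarray,
    repeats: int = 10, folds: int = 10, seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Repeated stratified k-fold CV of a full pipeline.

    One replicate = one held-out fold; ``repeats`` passes each reshuffle
    the fold assignment with seed ``seed + r``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    auc_values: list[float] = []
    f1_values: list[float] = []
    for r in range(repeats):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed + r)
        for train_idx, test_idx in splitter.split(X, y):
            pipe = pipeline_factory()
            pipe.fit(X[train_idx], y[train_idx])
            p = pipe.predict_proba_positive(X[test_idx])
            auc_values.append(auc(p, y[test_idx]))
            f1_values.append(f1((p >= threshold).astype(int), y[test_idx]))
    auc_arr, f1_arr = np.asarray(auc_values), np.asarray(f1_values)
    rho = 1.0 / (folds - 1)
    return EvalReport(
        metrics={
            "auc": MetricSummary(float(auc_arr.mean()),
                                 _normal_ci(auc_arr, rho), auc_arr),
            "f1": MetricSummary(float(f1_arr.mean()),
                                _normal_ci(f1_arr, rho), f1_arr),
        },
        config={"repeats": repeats, "folds": folds, "seed": seed,
                "threshold": threshold},
    )


def bootstrap_test_eval(model, X_test: np.ndarray, y_test: np.ndarray,
                        B: int = 200, seed: int = 0,
                        standardization=None) -> EvalReport:
    """Bootstrap the test set B times and summarise the AUC distribution.

    ``model`` is anything with ``predict_proba_positive`` or a precomputed
    score vector.  Resamples missing a class are redrawn.
    """
    y_test = np.asarray(y_test, dtype=int)
    if hasattr(model, "predict_proba_positive"):
        scores = np.asarray(model.predict_proba_positive(X_test), dtype=float)
    else:
        scores = np.asarray(model, dtype=float)
    rng = np.random.default_rng(seed)
    n = y_test.size
    values = np.empty(B)
    for b in range(B):
        for _ in range(100 * B):
            idx = rng.integers(0, n, size=n)
            if 0 < y_test[idx].sum() < n:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        values[b] = auc(scores[idx], y_test[idx])
    lo, hi = np.percentile(values, [2.5, 97.5])
    return EvalReport(
        metrics={"auc": MetricSummary(float(values.mean()),
                                      (float(lo), float(hi)), values)},
        config={"B": B, "seed": seed, "ci": "percentile"},
    )


def _delong_structural_components(scores: np.ndarray, labels: np.ndarray
                                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # Midrank placements via broadcasting (test sets here are modest).
    cmp = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of a single AUC estimate."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _, v10, v01 = _delong_structural_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> tuple[float, float]:
    """Paired DeLong test for AUC_a vs AUC_b on the same labelled samples.

    Returns (z, two-sided p); identical score vectors give (0, 1).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must share a shape")
    auc_a, v10_a, v01_a = _delong_structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_structural_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        return (0.0, 1.0) if delta == 0 else (np.inf * np.sign(delta), 0.0)
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def ttest_independent(values_a: Sequence[float], values_b: Sequence[float]
                      ) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def split_cohort(records: pd.DataFrame, ratio: float = 0.8, seed: int = 0,
                 size_bins: int = 3) -> tuple[list, list]:
    """Patient-level train/test split stratified by class and lesion size.

    ``records`` needs columns ``patient_id``, ``label`` and ``size`` (one
    row per lesion).  No patient appears in both outputs; the train
    fraction never exceeds ``ratio``; within each (class, size-bin)
    stratum the train share is as close to ``ratio`` as integer counts
    allow.
    """
    required = {"patient_id", "label", "size"}
    if missing := required - set(records.columns):
        raise ValueError(f"records missing columns: {sorted(missing)}")
    per_patient = records.groupby("patient_id").agg(
        label=("label", "max"), size=("size", "mean"))
    try:
        per_patient["size_bin"] = pd.qcut(per_patient["size"], size_bins,
                                          labels=False, duplicates="drop")
    except ValueError:
        per_patient["size_bin"] = 0
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for _, group in per_patient.groupby(["label", "size_bin"], sort=True):
        ids = list(group.index)
        rng.shuffle(ids)
        n_train = int(np.floor(ratio * len(ids) + 1e-9))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    if not test_ids or not train_ids:
        raise ValueError("infeasible stratification for the requested ratio")
    train_labels = per_patient.loc[train_ids, "label"]
    test_labels = per_patient.loc[test_ids, "label"]
    if train_labels.nunique() < 2 or test_labels.nunique() < 2:
        raise ValueError("a split side lost a class; add cases or change seed")
    return sorted(train_ids), sorted(test_ids)
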