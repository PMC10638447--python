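"""Leakage-free selector + classifier pipelines.

Every pipeline owns its preprocessing: ``fit`` standardizes on the
training rows it receives, selects features there, and trains the
classifier on the selected columns.  ``predict_proba_positive`` applies
the frozen training transforms to new rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import sparse_logistic as sl


@dataclass
class LsrPipeline:
    """Sparse logistic regression as selector and classifier in one fit.

    ``lam`` fixes the regularisation strength; when None it is set per
    fit to ``lam_frac * lambda_max`` of the training data, which adapts
    the penalty to the problem scale without retuning.
    """

    lam: float | None = None
    lam_frac: float = 0.05
    penalty: str = "l1"
    alpha: float = 0.5
    fit_intercept: bool = True
    max_iter: int = 5000
    tol: float = 1e-8

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LsrPipeline":
        self.standardization_ = sl.standardize_fit(X)
        Xs = sl.standardize_apply(X, self.standardization_)
        lam = self.lam if self.lam is not None else \
            self.lam_frac * sl.lambda_max(Xs, y, self.fit_intercept)
        self.model_ = sl.fit(Xs, y, lam=lam, penalty=self.penalty,
                             alpha=self.alpha, fit_intercept=self.fit_intercept,
                             max_iter=self.max_iter, tol=self.tol)
        return self

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        return sl.predict_proba(self.model_, X, self.standardization_)

    def selected(self, names: Sequence[str]) -> list[tuple[str, float, int]]:
        return sl.selected_features(self.model_, list(names))


@dataclass
class SelectThenClassify:
    """Generic two-stage pipeline: a column selector then any classifier.

    ``selector`` maps (X_standardized, y, X_raw) to kept column indices;
    ``classifier_factory`` builds a scikit-learn style estimator with
    ``fit`` and either ``predict_proba`` or ``decision_function``.
    """

    selector: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    classifier_factory: Callable[[], object]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SelectThenClassify":
        self.standardization_ = sl.standardize_fit(X)
        Xs = sl.standardize_apply(X, self.standardization_)
        self.columns_ = np.asarray(self.selector(Xs, y, X), dtype=int)
        if self.columns_.size == 0:       # degenerate selection: keep all
            self.columns_ = np.arange(X.shape[1])
        self.clf_ = self.classifier_factory()
        self.clf_.fit(Xs[:, self.columns_], y)
        return self

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        Xs = sl.standardize_apply(X, self.standardization_)[:, self.columns_]
        if hasattr(self.clf_, "predict_proba"):
            return np.asarray(self.clf_.predict_proba(Xs))[:, 1]
        z = np.asarray(self.clf_.decision_function(Xs), dtype=float)
        return sl.sigmoid(z)
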