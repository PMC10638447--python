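"""Bayesian optimisation of the L1 regularisation strength.

The objective is the mean AUC of a repeated, stratified, leakage-free
cross-validation of the sparse logistic model at a candidate lambda.  The
search runs in log10(lambda) space over a configurable box (default
[1e-6, 1e6]) with a Gaussian-process surrogate (Matern-5/2 kernel plus
estimated observation noise) and the expected-improvement acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold

from . import sparse_logistic as sl
from .evaluation import auc


@dataclass
class BOTrace:
    evaluated: list[tuple[float, float]]      # (log10_lambda, mean_auc)
    best_lambda: float
    best_auc: float
    seed: int
    bounds: tuple[float, float] = (1e-6, 1e6)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.evaluated, dtype=float)
        return arr[:, 0], arr[:, 1]


def cv_auc(lam: float, X: np.ndarray, y: np.ndarray, repeats: int = 10,
           folds: int = 5, seed: int = 0, penalty: str = "l1",
           max_iter: int = 3000, tol: float = 1e-7) -> float:
    """Mean held-out AUC of the sparse logistic model at one lambda.

    Standardization and fitting happen inside each training fold;
    deterministic for a fixed seed (repeat r shuffles with seed + r).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    minority = min(int(y.sum()), int((1 - y).sum()))
    if folds > minority:
        raise ValueError(f"folds={folds} exceeds minority class count {minority}")
    values = []
    for r in range(repeats):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed + r)
        for train_idx, test_idx in splitter.split(X, y):
            params = sl.standardize_fit(X[train_idx])
            Xtr = sl.standardize_apply(X[train_idx], params)
            model = sl.fit(Xtr, y[train_idx], lam=lam, penalty=penalty,
                           max_iter=max_iter, tol=tol)
            p = sl.predict_proba(model, X[test_idx], params)
            values.append(auc(p, y[test_idx]))
    return float(np.mean(values))


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float,
                          xi: float = 1e-3) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best - xi) / sigma
    return (mu - best - xi) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def maximize_1d(objective: Callable[[float], float],
                bounds: tuple[float, float] = (1e-6, 1e6),
                n_initial: int = 5, n_iterations: int = 25,
                seed: int = 0) -> BOTrace:
    """GP-EI maximisation of ``objective(lambda)`` over log10(lambda).

    ``n_initial`` stratified space-filling points, then ``n_iterations``
    EI acquisitions; the trace records every evaluation.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < low < high")
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    rng = np.random.default_rng(seed)

    # Stratified initial design: one uniform draw per equal-width stratum.
    edges = np.linspace(log_lo, log_hi, n_initial + 1)
    xs = [float(rng.uniform(edges[i], edges[i + 1])) for i in range(n_initial)]
    evaluated = [(x, float(objective(10.0 ** x))) for x in xs]

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * Matern(length_scale=0.1 * (log_hi - log_lo),
                       length_scale_bounds=(1e-3, 1e2), nu=2.5)
              + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-10, 1e-1)))
    for _ in range(n_iterations):
        pts = np.array([e[0] for e in evaluated])[:, None]
        vals = np.array([e[1] for e in evaluated])
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      n_restarts_optimizer=2,
                                      random_state=int(rng.integers(2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(pts, vals)
        cand = rng.uniform(log_lo, log_hi, size=512)[:, None]
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, vals.max())
        x_next = float(cand[int(np.argmax(ei)), 0])
        evaluated.append((x_next, float(objective(10.0 ** x_next))))

    best_idx = int(np.argmax([v for _, v in evaluated]))
    return BOTrace(evaluated=evaluated,
                   best_lambda=10.0 ** evaluated[best_idx][0],
                   best_auc=evaluated[best_idx][1], seed=seed, bounds=bounds)


def optimize(X: np.ndarray, y: np.ndarray,
             bounds: tuple[float, float] = (1e-6, 1e6),
             n_initial: int = 5, n_iterations: int = 25, seed: int = 0,
             repeats: int = 10, folds: int = 5, penalty: str = "l1",
             cv_kwargs: dict | None = None) -> BOTrace:
    """Bayesian optimisation of lambda against repeated CV AUC."""
    kwargs = dict(repeats=repeats, folds=folds, seed=seed, penalty=penalty)
    kwargs.update(cv_kwargs or {})

    def objective(lam: float) -> float:
        return cv_auc(lam, X, y, **kwargs)

    return maximize_1d(objective, bounds=bounds, n_initial=n_initial,
                       n_iterations=n_iterations, seed=seed)
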