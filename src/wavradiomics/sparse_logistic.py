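"""Sparse logistic regression for feature selection and classification.

The model is the MAP estimate of a logistic likelihood under a Laplacian
coefficient prior, i.e. the minimiser of

    f(theta) = sum_i -[y_i log p_i + (1 - y_i) log(1 - p_i)] + lam * ||theta||_1

with p_i = sigmoid(intercept + x_i . theta).  The intercept is unpenalised
(configurable off).  Ridge and elastic-net variants replace the penalty by
``lam * ||theta||_2^2`` and ``lam * (alpha ||theta||_1 + (1-alpha)
||theta||_2^2)`` respectively; a linear-response LASSO shares the solver.

Solver: monotone accelerated proximal gradient (FISTA with backtracking
line search and a monotonicity safeguard).  The L1 part is handled by the
exact soft-thresholding proximal map, so zero coefficients are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

_PENALTIES = ("l1", "l2", "elastic_net")
_PROB_CLIP = 1e-15


@dataclass
class StandardizationParams:
    """Per-feature training means and population standard deviations."""

    mu: np.ndarray
    sigma: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.zero_variance is None:
            self.zero_variance = self.sigma == 0
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)


@dataclass
class SparseLogisticModel:
    theta: np.ndarray
    intercept: float
    lam: float
    penalty: str = "l1"
    alpha: float = 0.5
    converged: bool = False
    iterations: int = 0
    final_objective: float = np.nan

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.theta))

    def to_json(self, names: list[str] | None = None) -> str:
        payload = {
            "lam": self.lam, "penalty": self.penalty, "alpha": self.alpha,
            "intercept": self.intercept, "converged": self.converged,
            "iterations": self.iterations, "final_objective": self.final_objective,
            "support_size": self.support_size,
        }
        if names is None:
            payload["theta"] = self.theta.tolist()
        else:
            payload["coefficients"] = {n: float(t) for n, t
                                       in zip(names, self.theta) if t != 0}
        return json.dumps(payload, indent=2)


def standardize_fit(X: np.ndarray) -> StandardizationParams:
    """Per-feature mean and population standard deviation of training rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in X")
    return StandardizationParams(mu=X.mean(axis=0), sigma=X.std(axis=0))


def standardize_apply(X: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """``(x - mu) / sigma`` columnwise; zero-variance columns map to 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != params.mu.size:
        raise ValueError("dimension mismatch with standardization params")
    sigma = np.where(params.zero_variance, 1.0, params.sigma)
    out = (X - params.mu) / sigma
    out[..., params.zero_variance] = 0.0
    return out


def sigmoid(z):
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def soft_threshold(v, t: float):
    """Elementwise ``sign(v) * max(|v| - t, 0)``."""
    v = np.asarray(v, dtype=float)
    out = np.sign(v) * np.maximum(np.abs(v) - t, 0.0)
    return out if out.ndim else float(out)


def _log_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def _penalty_value(theta: np.ndarray, lam: float, penalty: str, alpha: float) -> float:
    if penalty == "l1":
        return lam * float(np.abs(theta).sum())
    if penalty == "l2":
        return lam * float((theta ** 2).sum())
    if penalty == "elastic_net":
        return lam * float(alpha * np.abs(theta).sum()
                           + (1.0 - alpha) * (theta ** 2).sum())
    raise ValueError(f"unknown penalty {penalty!r}; choose from {_PENALTIES}")


def objective(theta: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray,
              lam: float, penalty: str = "l1", alpha: float = 0.5) -> float:
    """Penalised negative log-likelihood f(theta); intercept unpenalised."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    p = sigmoid(intercept + X @ theta)
    return _log_loss(p, y) + _penalty_value(theta, lam, penalty, alpha)


def lambda_max(X: np.ndarray, y: np.ndarray, fit_intercept: bool = True) -> float:
    """Smallest lam at which the L1 solution is exactly zero.

    With an unpenalised intercept the optimal intercept-only fit predicts
    the class prevalence, giving the stationarity bound
    ``||X.T (y - mean(y))||_inf``.
    """
    y = np.asarray(y, dtype=float)
    center = y.mean() if fit_intercept else 0.5
    return float(np.abs(X.T @ (y - center)).max())


def fit(X: np.ndarray, y: np.ndarray, lam: float, penalty: str = "l1",
        alpha: float = 0.5, fit_intercept: bool = True, max_iter: int = 20000,
        tol: float = 1e-9) -> SparseLogisticModel:
    """Fit the penalised logistic model by monotone FISTA with backtracking.

    ``X`` is expected standardized.  The returned ``converged`` flag is
    honest: False means the iteration budget ran out first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    m, n = X.shape
    if penalty not in _PENALTIES:
        raise ValueError(f"unknown penalty {penalty!r}")

    # Smooth part: log-loss (+ quadratic penalty portion); prox part: L1 portion.
    if penalty == "l1":
        l1_weight, l2_weight = lam, 0.0
    elif penalty == "l2":
        l1_weight, l2_weight = 0.0, lam
    else:
        l1_weight, l2_weight = lam * alpha, lam * (1.0 - alpha)

    def smooth(theta, b):
        p = sigmoid(b + X @ theta)
        return _log_loss(p, y) + l2_weight * float((theta ** 2).sum())

    def grad(theta, b):
        r = sigmoid(b + X @ theta) - y
        g_theta = X.T @ r + 2.0 * l2_weight * theta
        g_b = float(r.sum()) if fit_intercept else 0.0
        return g_theta, g_b

    def full_obj(theta, b):
        return smooth(theta, b) + l1_weight * float(np.abs(theta).sum())

    # Initial step from the logistic-loss Lipschitz bound ||X||_op^2 / 4.
    op2 = float(np.linalg.norm(X, 2) ** 2) if min(m, n) else 1.0
    op2 += m if fit_intercept else 0.0       # intercept column of ones
    step = 4.0 / max(op2 + 4.0 * l2_weight, 1e-12)

    theta = np.zeros(n)
    b = 0.0
    z_theta, z_b = theta.copy(), b
    t_mom = 1.0
    f_best = full_obj(theta, b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_theta, g_b = grad(z_theta, z_b)
        f_z = smooth(z_theta, z_b)
        while True:
            cand = soft_threshold(z_theta - step * g_theta, step * l1_weight)
            cand_b = z_b - step * g_b if fit_intercept else 0.0
            d_theta = cand - z_theta
            d_b = cand_b - z_b
            quad = (f_z + g_theta @ d_theta + g_b * d_b
                    + (d_theta @ d_theta + d_b * d_b) / (2.0 * step))
            if smooth(cand, cand_b) <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            step *= 0.5
        f_cand = full_obj(cand, cand_b)
        if f_cand <= f_best + 1e-15 * max(1.0, abs(f_best)):
            # Accepted step; standard FISTA momentum around the new iterate.
            rel_change = (f_best - f_cand) / max(1.0, abs(f_best))
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2))
            mom = (t_mom - 1.0) / t_next
            z_theta = cand + mom * (cand - theta)
            z_b = cand_b + mom * (cand_b - b)
            theta, b, f_best, t_mom = cand, cand_b, min(f_cand, f_best), t_next
            if rel_change < tol and it > 1:
                converged = True
                break
        else:
            # Momentum overshoot increased the objective: restart from the
            # best iterate (keeps accepted objectives non-increasing).
            z_theta, z_b, t_mom = theta.copy(), b, 1.0

    return SparseLogisticModel(theta=theta, intercept=float(b), lam=float(lam),
                               penalty=penalty, alpha=alpha, converged=converged,
                               iterations=it, final_objective=f_best)


def kkt_residual(model: SparseLogisticModel, X: np.ndarray, y: np.ndarray) -> float:
    """Max violation of the L1 optimality conditions (0 at an exact optimum).

    Zero coordinates require ``|grad_j| <= lam``; nonzero coordinates
    require ``grad_j = -lam * sign(theta_j)``.
    """
    if model.penalty != "l1":
        raise ValueError("KKT residual is defined for the l1 penalty")
    r = sigmoid(model.intercept + X @ model.theta) - np.asarray(y, float)
    g = X.T @ r
    zero = model.theta == 0
    res_zero = np.maximum(np.abs(g[zero]) - model.lam, 0.0)
    res_nz = np.abs(g[~zero] + model.lam * np.sign(model.theta[~zero]))
    parts = [res_zero, res_nz]
    return float(max((p.max() for p in parts if p.size), default=0.0))


def selected_features(model: SparseLogisticModel, names: list[str]
                      ) -> list[tuple[str, float, int]]:
    """Nonzero coefficients as (name, coefficient, rank), rank 1 = largest |.|."""
    nz = np.nonzero(model.theta)[0]
    order = nz[np.argsort(-np.abs(model.theta[nz]), kind="stable")]
    return [(names[j], float(model.theta[j]), rank + 1)
            for rank, j in enumerate(order)]


def predict_proba(model: SparseLogisticModel, X_new: np.ndarray,
                  standardization: StandardizationParams | None = None) -> np.ndarray:
    """P(y=1 | x) for new rows; applies training standardization if given."""
    X_new = np.asarray(X_new, dtype=float)
    if standardization is not None:
        X_new = standardize_apply(X_new, standardization)
    if X_new.shape[-1] != model.theta.size:
        raise ValueError("dimension mismatch with model coefficients")
    return sigmoid(model.intercept + X_new @ model.theta)


def fit_lasso_linear(X: np.ndarray, y: np.ndarray, lam: float,
                     fit_intercept: bool = False, max_iter: int = 20000,
                     tol: float = 1e-10) -> np.ndarray:
    """Linear-response LASSO: minimise ``||y - X theta||^2 + lam ||theta||_1``.

    Shares the proximal machinery with the logistic solver but with the
    squared-error gradient.  Used as the LASSO selection baseline; no
    intercept by default (fit on standardized data).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit_intercept:
        y = y - y.mean()
    theta = np.zeros(X.shape[1])
    lip = 2.0 * float(np.linalg.norm(X, 2) ** 2) if X.size else 1.0
    step = 1.0 / max(lip, 1e-12)
    z = theta.copy()
    t_mom = 1.0

    def obj(th):
        r = y - X @ th
        return float(r @ r) + lam * float(np.abs(th).sum())

    f_best = obj(theta)
    for _ in range(max_iter):
        g = 2.0 * (X.T @ (X @ z - y))
        cand = soft_threshold(z - step * g, step * lam)
        f_cand = obj(cand)
        if f_cand <= f_best + 1e-15 * max(1.0, abs(f_best)):
            rel = (f_best - f_cand) / max(1.0, abs(f_best))
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2))
            z = cand + ((t_mom - 1.0) / t_next) * (cand - theta)
            theta, f_best, t_mom = cand, min(f_cand, f_best), t_next
            if rel < tol:
                break
        else:
            z, t_mom = theta.copy(), 1.0
    return theta
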