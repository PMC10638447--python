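"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible (explicit loops,
exhaustive enumeration) and shares no code with the package internals it
checks.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Separable periodic convolution (wavelet oracle)
# ---------------------------------------------------------------------------

def conv1d_periodic_loop(x: np.ndarray, h: np.ndarray, axis: int) -> np.ndarray:
    """y[n] = sum_k h[k] x[(n - k) mod N] along one axis, triple loop."""
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    y = np.zeros_like(x)
    for i in range(n):
        for k in range(len(h)):
            y[i] += h[k] * x[(i - k) % n]
    return np.moveaxis(y, 0, axis)


def separable_subband_loop(vol: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                           label: str) -> np.ndarray:
    out = vol
    for axis, letter in enumerate(label):
        out = conv1d_periodic_loop(out, lo if letter == "L" else hi, axis)
    return out


# ---------------------------------------------------------------------------
# Texture-matrix enumeration oracles
# ---------------------------------------------------------------------------

_NEIGHBORS_26 = [(dx, dy, dz)
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                 if (dx, dy, dz) != (0, 0, 0)]


def _in_grid(v, shape):
    return all(0 <= v[a] < shape[a] for a in range(3))


def glcm_oracle(levels: np.ndarray, mask: np.ndarray, ng: int,
                direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction by enumeration."""
    P = np.zeros((ng, ng))
    shape = levels.shape
    for v in np.ndindex(shape):
        if not mask[v]:
            continue
        for off in (direction, tuple(-c for c in direction)):
            w = tuple(v[a] + off[a] for a in range(3))
            if _in_grid(w, shape) and mask[w]:
                P[levels[v] - 1, levels[w] - 1] += 1
    return P


def glrlm_oracle(levels: np.ndarray, mask: np.ndarray, ng: int, nr: int,
                 direction: tuple[int, int, int]) -> np.ndarray:
    """Maximal same-level runs along one direction by enumeration."""
    P = np.zeros((ng, nr))
    shape = levels.shape
    for v in np.ndindex(shape):
        if not mask[v]:
            continue
        prev = tuple(v[a] - direction[a] for a in range(3))
        if _in_grid(prev, shape) and mask[prev] and levels[prev] == levels[v]:
            continue    # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[a] + direction[a] for a in range(3))
            if not (_in_grid(nxt, shape) and mask[nxt]
                    and levels[nxt] == levels[cur]):
                break
            length += 1
            cur = nxt
        P[levels[v] - 1, length - 1] += 1
    return P


def glszm_oracle(levels: np.ndarray, mask: np.ndarray, ng: int, ns: int
                 ) -> np.ndarray:
    """26-connected same-level zones by flood fill."""
    P = np.zeros((ng, ns))
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    for v in np.ndindex(shape):
        if not mask[v] or seen[v]:
            continue
        g = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in _NEIGHBORS_26:
                w = tuple(cur[a] + off[a] for a in range(3))
                if (_in_grid(w, shape) and mask[w] and not seen[w]
                        and levels[w] == g):
                    seen[w] = True
                    stack.append(w)
        P[g - 1, size - 1] += 1
    return P


def gldm_oracle(levels: np.ndarray, mask: np.ndarray, ng: int, nd: int,
                alpha: int = 0) -> np.ndarray:
    """Dependence counts (center voxel included in the size)."""
    P = np.zeros((ng, nd))
    shape = levels.shape
    for v in np.ndindex(shape):
        if not mask[v]:
            continue
        dep = 1
        for off in _NEIGHBORS_26:
            w = tuple(v[a] + off[a] for a in range(3))
            if (_in_grid(w, shape) and mask[w]
                    and abs(int(levels[w]) - int(levels[v])) <= alpha):
                dep += 1
        P[levels[v] - 1, dep - 1] += 1
    return P


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def auc_pair_count(scores, labels) -> float:
    """Exhaustive positive-negative pair counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def delong_variance_naive(scores, labels) -> float:
    """DeLong AUC variance from explicitly computed placement values."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    v10 = np.array([np.mean([psi(p, q) for q in neg]) for p in pos])
    v01 = np.array([np.mean([psi(p, q) for p in pos]) for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def logistic_objective_grid_min(X, y, lam, grid=np.linspace(-5, 5, 401)):
    """Dense grid search over 2D theta for the L1 logistic objective
    (no intercept).  Returns the minimal objective value on the grid."""
    t0, t1 = np.meshgrid(grid, grid, indexing="ij")
    thetas = np.stack([t0.ravel(), t1.ravel()])        # (2, G)
    z = X @ thetas                                     # (M, G)
    p = 1.0 / (1.0 + np.exp(-z))
    p = np.clip(p, 1e-15, 1 - 1e-15)
    y = np.asarray(y, float)[:, None]
    nll = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=0)
    obj = nll + lam * np.abs(thetas).sum(axis=0)
    return float(obj.min())


def lasso_objective_grid_min(X, y, lam, grid=np.linspace(-5, 5, 401)):
    """Dense grid search for the linear LASSO objective over 2D theta."""
    t0, t1 = np.meshgrid(grid, grid, indexing="ij")
    thetas = np.stack([t0.ravel(), t1.ravel()])
    resid = np.asarray(y, float)[:, None] - X @ thetas
    obj = (resid ** 2).sum(axis=0) + lam * np.abs(thetas).sum(axis=0)
    return float(obj.min())
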