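"""Gray-level texture matrices (GLCM, GLRLM, GLSZM, GLDM) and their features.

All matrices operate on a :class:`QuantizedROI`: a discretised gray-level
grid (levels 1..Ng inside the mask, 0 outside).  Conventions:

- GLCM / GLRLM use the 13 unique 3D direction offsets (symmetric closure
  26); per-direction feature values are averaged over directions.
- GLCM matrices are symmetrised (``P + P.T``).
- GLSZM zones and GLDM dependences use 26-connectivity.
- GLDM dependence counts a neighbour as dependent when
  ``|level(center) - level(neighbour)| <= alpha`` (default 0); the
  dependence size includes the center voxel, so its minimum is 1.
- Runs and zones never cross the mask boundary.

The roster totals 68 features: 22 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM,
following the de-facto standard radiomics definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# 13 unique offsets: first nonzero component positive.
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)
DIRECTIONS_26 = DIRECTIONS_13 + tuple(tuple(-c for c in d) for d in DIRECTIONS_13)


@dataclass
class QuantizedROI:
    """Discretised ROI: integer levels 1..Ng in-mask, 0 outside."""

    levels: np.ndarray        # int array, full crop shape
    mask: np.ndarray          # bool array, same shape
    ng: int
    bin_width: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        if self.ng < 1:
            raise ValueError("Ng must be >= 1")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.ng):
            raise ValueError("in-mask levels must lie in [1, Ng]")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _paired_slices(shape: tuple[int, ...], offset: tuple[int, ...]
                   ) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    """Slices (a, b) so arr[a] is voxel v and arr[b] is voxel v+offset."""
    sa, sb = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            sa.append(slice(0, n - o))
            sb.append(slice(o, n))
        else:
            sa.append(slice(-o, n))
            sb.append(slice(0, n + o))
    return tuple(sa), tuple(sb)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def glcm_matrices(q: QuantizedROI) -> np.ndarray:
    """Symmetric co-occurrence counts, shape (13, Ng, Ng)."""
    out = np.zeros((len(DIRECTIONS_13), q.ng, q.ng))
    for d, off in enumerate(DIRECTIONS_13):
        sa, sb = _paired_slices(q.levels.shape, off)
        valid = q.mask[sa] & q.mask[sb]
        i = q.levels[sa][valid] - 1
        j = q.levels[sb][valid] - 1
        P = np.zeros((q.ng, q.ng))
        np.add.at(P, (i, j), 1.0)
        out[d] = P + P.T
    return out


def _shift_full(arr: np.ndarray, offset: tuple[int, ...], fill) -> np.ndarray:
    """Value at v - offset placed at v (out-of-grid becomes ``fill``)."""
    out = np.full_like(arr, fill)
    sa, sb = _paired_slices(arr.shape, offset)
    out[sb] = arr[sa]
    return out


def glrlm_matrices(q: QuantizedROI) -> np.ndarray:
    """Run-length counts per direction, shape (13, Ng, Nr)."""
    nr = max(q.levels.shape)
    out = np.zeros((len(DIRECTIONS_13), q.ng, nr))
    for d, off in enumerate(DIRECTIONS_13):
        sa, sb = _paired_slices(q.levels.shape, off)
        cont = np.zeros(q.levels.shape, dtype=bool)   # run continues v -> v+off
        cont[sa] = (q.levels[sa] == q.levels[sb]) & q.mask[sa] & q.mask[sb]
        # Run length from v to the run end, by fixed-point iteration.
        run = np.ones(q.levels.shape, dtype=np.int64)
        while True:
            nxt = np.zeros_like(run)
            nxt[sa] = run[sb]
            new = 1 + np.where(cont, nxt, 0)
            if np.array_equal(new, run):
                break
            run = new
        starts = q.mask & ~_shift_full(cont, off, False)
        lengths = run[starts]
        levels = q.levels[starts]
        np.add.at(out[d], (levels - 1, lengths - 1), 1.0)
    return out


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Size-zone counts, shape (Ng, Ns); zones are 26-connected."""
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []    # (level, size)
    for g in range(1, q.ng + 1):
        labelled, n = ndimage.label((q.levels == g) & q.mask, structure=structure)
        if n:
            sizes = np.bincount(labelled.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    ns = max((s for _, s in zones), default=1)
    out = np.zeros((q.ng, ns))
    for g, s in zones:
        out[g - 1, s - 1] += 1.0
    return out


def gldm_matrix(q: QuantizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts, shape (Ng, Nd); 26-neighbourhood, center included."""
    dep = np.zeros(q.levels.shape, dtype=np.int64)
    for off in DIRECTIONS_26:
        sa, sb = _paired_slices(q.levels.shape, off)
        dependent = ((np.abs(q.levels[sa] - q.levels[sb]) <= alpha)
                     & q.mask[sa] & q.mask[sb])
        dep[sa] += dependent
    sizes = dep[q.mask] + 1
    levels = q.levels[q.mask]
    nd = int(sizes.max()) if sizes.size else 1
    out = np.zeros((q.ng, nd))
    np.add.at(out, (levels - 1, sizes - 1), 1.0)
    return out


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

N_TEXTURE_FEATURES = (len(GLCM_FEATURES) + len(GLRLM_FEATURES)
                      + len(GLSZM_FEATURES) + len(GLDM_FEATURES))    # 68


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm_features_single(P: np.ndarray, ng: int) -> dict[str, float]:
    total = P.sum()
    p = P / total if total > 0 else P
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    # symmetric matrix: py == px, mu_y == mu_x
    diff = np.abs(ii - jj)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, diff.ravel(), p.ravel())
    k_diff = np.arange(ng)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)

    joint_entropy = _entropy2(p.ravel())
    hx = _entropy2(px)
    # HXY1/HXY2 use the product of marginals.
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    da = float((k_diff * p_diff).sum())
    corr_num = float((p * ii * jj).sum()) - mu_x * mu_x
    correlation = 1.0 if sig_x == 0 else corr_num / (sig_x * sig_x)
    imc1 = 0.0 if max(hx, hx) == 0 else (joint_entropy - hxy1) / max(hx, hx)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float((p * (ii + jj - 2 * mu_x) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu_x) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu_x) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": joint_entropy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
    }


def glcm_features(q: QuantizedROI) -> dict[str, float]:
    mats = glcm_matrices(q)
    acc = {name: 0.0 for name in GLCM_FEATURES}
    used = 0
    for P in mats:
        if P.sum() == 0:
            continue
        vals = _glcm_features_single(P, q.ng)
        for name in GLCM_FEATURES:
            acc[name] += vals[name]
        used += 1
    n = max(used, 1)
    return {name: acc[name] / n for name in GLCM_FEATURES}


def _size_weighted_features(P: np.ndarray, n_voxels: int, names: tuple[str, ...],
                            size_word: str) -> dict[str, float]:
    """Shared arithmetic for GLRLM/GLSZM/GLDM-style matrices.

    ``P[i-1, j-1]`` counts elements with gray level i and size/length j.
    """
    ng, ns = P.shape
    nz_total = P.sum()
    if nz_total == 0:
        return {name: 0.0 for name in names}
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ns + 1)[None, :]
    pg = P.sum(axis=1)       # per gray level
    ps = P.sum(axis=0)       # per size
    pn = P / nz_total
    mu_i = float((pn * i).sum())
    mu_j = float((pn * j).sum())
    vals = {
        "small": float((P / j ** 2).sum() / nz_total),
        "large": float((P * j ** 2).sum() / nz_total),
        "gln": float((pg ** 2).sum() / nz_total),
        "glnn": float((pg ** 2).sum() / nz_total ** 2),
        "sn": float((ps ** 2).sum() / nz_total),
        "snn": float((ps ** 2).sum() / nz_total ** 2),
        "perc": float(nz_total / n_voxels),
        "glv": float((pn * (i - mu_i) ** 2).sum()),
        "sv": float((pn * (j - mu_j) ** 2).sum()),
        "entropy": _entropy2(pn.ravel()),
        "lgl": float((P / i ** 2).sum() / nz_total),
        "hgl": float((P * i ** 2).sum() / nz_total),
        "slgl": float((P / (i ** 2 * j ** 2)).sum() / nz_total),
        "shgl": float((P * i ** 2 / j ** 2).sum() / nz_total),
        "llgl": float((P * j ** 2 / i ** 2).sum() / nz_total),
        "lhgl": float((P * i ** 2 * j ** 2).sum() / nz_total),
    }
    key_by_name = {
        f"Short{size_word}Emphasis": "small", f"Small{size_word}Emphasis": "small",
        f"Long{size_word}Emphasis": "large", f"Large{size_word}Emphasis": "large",
        "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
        "RunLengthNonUniformity": "sn", "RunLengthNonUniformityNormalized": "snn",
        "SizeZoneNonUniformity": "sn", "SizeZoneNonUniformityNormalized": "snn",
        "DependenceNonUniformity": "sn", "DependenceNonUniformityNormalized": "snn",
        "RunPercentage": "perc", "ZonePercentage": "perc",
        "GrayLevelVariance": "glv",
        "RunVariance": "sv", "ZoneVariance": "sv", "DependenceVariance": "sv",
        "RunEntropy": "entropy", "ZoneEntropy": "entropy",
        "DependenceEntropy": "entropy",
        "LowGrayLevelRunEmphasis": "lgl", "LowGrayLevelZoneEmphasis": "lgl",
        "LowGrayLevelEmphasis": "lgl",
        "HighGrayLevelRunEmphasis": "hgl", "HighGrayLevelZoneEmphasis": "hgl",
        "HighGrayLevelEmphasis": "hgl",
        f"Short{size_word}LowGrayLevelEmphasis": "slgl",
        f"Small{size_word}LowGrayLevelEmphasis": "slgl",
        f"SmallDependenceLowGrayLevelEmphasis": "slgl",
        f"Short{size_word}HighGrayLevelEmphasis": "shgl",
        f"Small{size_word}HighGrayLevelEmphasis": "shgl",
        f"SmallDependenceHighGrayLevelEmphasis": "shgl",
        f"Long{size_word}LowGrayLevelEmphasis": "llgl",
        f"Large{size_word}LowGrayLevelEmphasis": "llgl",
        f"LargeDependenceLowGrayLevelEmphasis": "llgl",
        f"Long{size_word}HighGrayLevelEmphasis": "lhgl",
        f"Large{size_word}HighGrayLevelEmphasis": "lhgl",
        f"LargeDependenceHighGrayLevelEmphasis": "lhgl",
        "SmallDependenceEmphasis": "small", "LargeDependenceEmphasis": "large",
    }
    return {name: vals[key_by_name[name]] for name in names}


def glrlm_features(q: QuantizedROI) -> dict[str, float]:
    mats = glrlm_matrices(q)
    acc = {name: 0.0 for name in GLRLM_FEATURES}
    used = 0
    for P in mats:
        if P.sum() == 0:
            continue
        vals = _size_weighted_features(P, q.n_voxels, GLRLM_FEATURES, "Run")
        for name in GLRLM_FEATURES:
            acc[name] += vals[name]
        used += 1
    n = max(used, 1)
    return {name: acc[name] / n for name in GLRLM_FEATURES}


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    return _size_weighted_features(glszm_matrix(q), q.n_voxels,
                                   GLSZM_FEATURES, "Area")


def gldm_features(q: QuantizedROI, alpha: int = 0) -> dict[str, float]:
    return _size_weighted_features(gldm_matrix(q, alpha=alpha), q.n_voxels,
                                   GLDM_FEATURES, "Dependence")


def texture_features(q: QuantizedROI, alpha: int = 0
                     ) -> tuple[list[str], np.ndarray]:
    """The full 68-value texture roster as (names, values).

    Names are prefixed with the matrix type (``glcm_Contrast`` etc.).
    """
    names: list[str] = []
    values: list[float] = []
    for prefix, feats in (
        ("glcm", glcm_features(q)),
        ("glrlm", glrlm_features(q)),
        ("glszm", glszm_features(q)),
        ("gldm", gldm_features(q, alpha=alpha)),
    ):
        for name, val in feats.items():
            names.append(f"{prefix}_{name}")
            values.append(val)
    return names, np.asarray(values)
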