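"""Undecimated separable 3D wavelet decomposition.

One decomposition level turns a volume into 8 subbands (LLL ... HHH), one
per combination of the low- and high-pass analysis filters applied along
the three axes.  The transform is *undecimated* (stationary): no
downsampling, so every subband keeps the input shape and stays voxel-
aligned with the ROI mask — a requirement for masked per-subband feature
extraction.

Label convention: in a label ``XYZ`` the letter ``X`` is the filter applied
along axis 0, ``Y`` along axis 1 and ``Z`` along axis 2 of the ``(x, y, z)``
voxel grid.

Filtering convention: plain discrete convolution
``y[n] = sum_k h[k] * x[n - k]`` with either periodic (default) or
symmetric boundary extension.  Levels above 1 re-decompose the previous
LLL band with a-trous (zero-upsampled) filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pywt

from .io_volumes import ImageVolume

SUBBAND_LABELS = tuple("".join(c) for c in product("LH", repeat=3))
# ('LLL', 'LLH', 'LHL', 'LHH', 'HLL', 'HLH', 'HHL', 'HHH')

_FAMILIES = ("haar", "db2", "db4", "db7", "sym4", "coif1", "bior6.8", "rbio6.8")


@dataclass
class SubbandVolume:
    """One wavelet-filtered volume, same shape as its source."""

    voxels: np.ndarray
    label: str                       # e.g. "LHL"
    family: str
    level: int
    mode: str = "periodic"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def supported_families() -> list[str]:
    """Wavelet families accepted by :func:`decompose` (duplicate-free)."""
    return list(_FAMILIES)


def _filters(family: str) -> tuple[np.ndarray, np.ndarray]:
    if family not in _FAMILIES:
        raise ValueError(f"unsupported wavelet family {family!r}; "
                         f"choose one of {_FAMILIES}")
    w = pywt.Wavelet(family)
    return np.asarray(w.dec_lo, dtype=float), np.asarray(w.dec_hi, dtype=float)


def _upsample(h: np.ndarray, level: int) -> np.ndarray:
    """A-trous upsampling: insert 2**(level-1) - 1 zeros between taps."""
    if level <= 1:
        return h
    step = 2 ** (level - 1)
    out = np.zeros((len(h) - 1) * step + 1)
    out[::step] = h
    return out


def _filter_axis(x: np.ndarray, h: np.ndarray, axis: int, mode: str) -> np.ndarray:
    """1D convolution y[n] = sum_k h[k] x[n-k] along one axis."""
    if mode == "periodic":
        y = np.zeros_like(x)
        for k, hk in enumerate(h):
            y += hk * np.roll(x, k, axis=axis)
        return y
    if mode == "symmetric":
        length = len(h)
        pad = [(0, 0)] * x.ndim
        pad[axis] = (length - 1, 0)
        xp = np.pad(x, pad, mode="symmetric")
        y = np.zeros_like(x)
        sl = [slice(None)] * x.ndim
        for k, hk in enumerate(h):
            sl[axis] = slice(length - 1 - k, xp.shape[axis] - k)
            y += hk * xp[tuple(sl)]
        return y
    raise ValueError(f"unknown boundary mode {mode!r} (periodic|symmetric)")


def decompose(
    vol: ImageVolume | np.ndarray,
    family: str = "haar",
    level: int = 1,
    mode: str = "periodic",
) -> list[SubbandVolume]:
    """Decompose a volume into 8 subbands per level.

    Returns ``8 * level`` subbands ordered by level then label; each level
    re-decomposes the previous level's LLL band with a-trous filters.
    """
    voxels = vol.voxels if isinstance(vol, ImageVolume) else np.asarray(vol, float)
    if voxels.ndim != 3:
        raise ValueError("decompose expects a 3D volume")
    if level < 1:
        raise ValueError("level must be >= 1")
    lo, hi = _filters(family)
    # Periodic extension is well defined for any size (indices wrap);
    # symmetric extension needs the grid to cover the filter support.
    if mode == "symmetric" and min(voxels.shape) < len(_upsample(lo, level)):
        raise ValueError(
            f"volume shape {voxels.shape} smaller than the level-{level} "
            f"filter support ({len(_upsample(lo, level))} taps) for {family!r}")

    out: list[SubbandVolume] = []
    approx = voxels
    for lev in range(1, level + 1):
        lo_l, hi_l = _upsample(lo, lev), _upsample(hi, lev)
        # Precompute the two filtered versions per axis, reusing partial results.
        bands: dict[str, np.ndarray] = {"": approx}
        for axis in range(3):
            new: dict[str, np.ndarray] = {}
            for prefix, arr in bands.items():
                new[prefix + "L"] = _filter_axis(arr, lo_l, axis, mode)
                new[prefix + "H"] = _filter_axis(arr, hi_l, axis, mode)
            bands = new
        for label in SUBBAND_LABELS:
            out.append(SubbandVolume(voxels=bands[label], label=label,
                                     family=family, level=lev, mode=mode))
        approx = bands["LLL"]
    return out
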