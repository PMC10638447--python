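"""Synthetic stand-ins for the private clinical cohort.

Two generators, both pure functions of (spec, seed):

- multiphase lesion *phantoms*: a smooth abdominal-CT-like background with
  an ellipsoidal lesion whose texture statistics depend on the class.
  Positive lesions carry a spatially correlated Gaussian random field
  (longer correlation length) plus an arterial-phase enhancement offset;
  negative lesions carry uncorrelated noise of matched amplitude.  The
  class signal therefore lives in texture (co-occurrence structure), not
  in mean intensity, which is what wavelet/texture features measure.
- high-dimensional *feature tables* with M << N rows-to-features, an
  equicorrelated Gaussian design, and a small known true support driving
  the labels through a logistic link — ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_volumes import (ImageVolume, ROIMask, PHASES, write_manifest,
                         write_mask, write_volume)

HU_BOUNDS = (-200.0, 400.0)


@dataclass
class PhantomSpec:
    """Geometry, intensity and per-class texture parameters of a phantom."""

    grid_shape: tuple[int, int, int] = (36, 36, 28)
    spacing: tuple[float, float, float] = (0.85, 0.85, 1.25)   # mm, anisotropic
    background_hu: float = 55.0
    background_noise_sd: float = 5.0
    lesion_hu: float = 90.0
    lesion_semiaxes_mm: tuple[float, float, float] = (7.0, 6.0, 5.0)
    semiaxes_jitter: float = 0.15       # relative, per case
    # texture: amplitude of the in-lesion random field (HU) and the
    # Gaussian correlation length (mm) per class
    texture_amplitude: tuple[float, float] = (25.0, 25.0)      # (class0, class1)
    correlation_length_mm: tuple[float, float] = (0.0, 2.5)    # 0 = white noise
    # per-phase mean enhancement offsets (HU), class 0 then class 1;
    # class 1 mimics arterial hyperenhancement with delayed washout
    enhancement: tuple[tuple[float, float, float],
                       tuple[float, float, float]] = ((8.0, 15.0, 15.0),
                                                      (45.0, 10.0, -5.0))

    def __post_init__(self) -> None:
        if min(self.lesion_semiaxes_mm) * 2 < 5.0:
            raise ValueError("lesion diameter must be at least 5 mm")
        for ax, n, sp in zip(self.lesion_semiaxes_mm, self.grid_shape,
                             self.spacing):
            if 2 * ax >= n * sp:
                raise ValueError("lesion does not fit inside the grid")


@dataclass
class SyntheticFeatureSpec:
    """Spec of the M << N sparse-ground-truth feature table."""

    m: int = 300
    n: int = 500
    k_true: int = 10
    coefficient_magnitude: float = 1.0
    rho: float = 0.2           # equicorrelation between features
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true > self.n or self.m < 10 or not (0 <= self.rho < 1):
            raise ValueError("invalid synthetic feature spec")


def _correlated_field(shape, corr_len_vox: float, rng) -> np.ndarray:
    """Unit-variance Gaussian field; corr_len 0 means white noise."""
    noise = rng.standard_normal(shape)
    if corr_len_vox <= 0:
        return noise
    smooth = ndimage.gaussian_filter(noise, sigma=corr_len_vox, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_phantom_case(spec: PhantomSpec, class_label: int, seed: int
                      ) -> tuple[dict[str, ImageVolume], ROIMask, int]:
    """One co-registered 3-phase case plus its exact ellipsoid mask."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape
    sp = np.array(spec.spacing)
    center = (np.array(shape) - 1) / 2.0 * sp
    jitter = 1.0 + spec.semiaxes_jitter * rng.uniform(-1, 1, size=3)
    semiaxes = np.array(spec.lesion_semiaxes_mm) * jitter

    coords = np.stack(np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)],
                                  indexing="ij"))
    dist2 = sum(((coords[a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
    mask = dist2 <= 1.0
    if not mask.any():
        raise ValueError("lesion fell below the grid resolution")

    # Smooth background shared across phases (same anatomy).
    background = (spec.background_hu
                  + 8.0 * _correlated_field(shape, 6.0 / sp.mean(), rng))
    texture = _correlated_field(
        shape, spec.correlation_length_mm[class_label] / sp.mean(), rng)
    amplitude = spec.texture_amplitude[class_label]

    phases: dict[str, ImageVolume] = {}
    for idx, ph in enumerate(PHASES):
        offset = spec.enhancement[class_label][idx]
        vox = background + spec.background_noise_sd * rng.standard_normal(shape)
        vox[mask] = (spec.lesion_hu + offset
                     + amplitude * texture[mask]
                     + spec.background_noise_sd * rng.standard_normal(int(mask.sum())))
        vox = np.clip(vox, *HU_BOUNDS)
        phases[ph] = ImageVolume(voxels=vox, spacing=tuple(sp), phase=ph)
    roi = ROIMask(voxels=mask, spacing=tuple(sp))
    return phases, roi, class_label


def generate_cases(n_cases: int, prevalence: float, spec: PhantomSpec, seed: int
                   ) -> list[tuple[dict[str, ImageVolume], ROIMask, int]]:
    """In-memory cohort: ``round(prevalence * n)`` positive cases."""
    if n_cases < 4:
        raise ValueError("need at least 4 cases")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    n_pos = int(round(prevalence * n_cases))
    labels = np.array([1] * n_pos + [0] * (n_cases - n_pos))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return [make_phantom_case(spec, int(lab), seed=int(seed + 1000 + i))
            for i, lab in enumerate(labels)]


def make_cohort(n_cases: int, prevalence: float, spec: PhantomSpec, seed: int,
                out_dir: str | Path) -> pd.DataFrame:
    """Write a labelled phantom cohort and its manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (phases, mask, label) in enumerate(
            generate_cases(n_cases, prevalence, spec, seed)):
        case_id = f"case{i:03d}"
        row = {"case_id": case_id, "label": label}
        for ph in PHASES:
            path = out / f"{case_id}_{ph}.nii.gz"
            write_volume(phases[ph], path)
            row[ph] = path.name
        mask_path = out / f"{case_id}_mask.nii.gz"
        write_mask(mask, mask_path)
        row["mask"] = mask_path.name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out / "manifest.csv")
    return manifest


def make_feature_dataset(spec: SyntheticFeatureSpec, return_theta: bool = False):
    """Equicorrelated Gaussian design with a sparse logistic ground truth.

    Returns (X, y, true support indices), plus ``theta*`` itself when
    ``return_theta`` is set.  ``theta*`` has ``k_true`` nonzeros of the
    stated magnitude with random signs at random positions;
    ``y ~ Bernoulli(sigmoid(X theta*))``.
    """
    rng = np.random.default_rng(spec.seed)
    shared = rng.standard_normal((spec.m, 1))
    unique = rng.standard_normal((spec.m, spec.n))
    X = math.sqrt(spec.rho) * shared + math.sqrt(1.0 - spec.rho) * unique
    support = np.sort(rng.choice(spec.n, size=spec.k_true, replace=False))
    theta = np.zeros(spec.n)
    theta[support] = spec.coefficient_magnitude * rng.choice([-1.0, 1.0],
                                                             size=spec.k_true)
    logits = X @ theta
    y = (rng.uniform(size=spec.m) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    if return_theta:
        return X, y, support, theta
    return X, y, support
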