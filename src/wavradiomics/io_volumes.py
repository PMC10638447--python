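"""Reading, writing and geometric preprocessing of 3D CT volumes and masks.

Conventions
-----------
Voxel arrays are indexed ``(x, y, z)`` with 0-based indices; world
coordinates are ``origin + index * spacing`` (mm).  On-disk layouts are
converted to this convention on read regardless of the file format.
Contrast phases are assumed pre-registered: the loader verifies equal
shape and spacing across phases and raises otherwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

PHASES = ("arterial", "venous", "delayed")
_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".nhdr")


@dataclass
class ImageVolume:
    """A 3D scalar grid in Hounsfield units with physical geometry."""

    voxels: np.ndarray          # float array, shape (nx, ny, nz)
    spacing: tuple[float, float, float]   # mm per voxel along (x, y, z)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be positive: {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROIMask:
    """Binary lesion mask aligned with an :class:`ImageVolume`."""

    voxels: np.ndarray          # bool array, shape (nx, ny, nz)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) > 0.5
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be positive: {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


def _check_path(path: str | os.PathLike) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    name = p.name.lower()
    if not any(name.endswith(suf) for suf in _SUPPORTED_SUFFIXES):
        raise ValueError(f"unsupported volume format: {p.name} "
                         f"(expected one of {_SUPPORTED_SUFFIXES})")
    return p


def read_volume(path: str | os.PathLike, phase: str | None = None) -> ImageVolume:
    """Read a NIfTI or NRRD file into the package's (x, y, z) convention."""
    p = _check_path(path)
    img = sitk.ReadImage(str(p))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D payload, got {img.GetDimension()}D: {p}")
    arr = sitk.GetArrayFromImage(img)            # (z, y, x)
    voxels = np.asarray(arr, dtype=float).transpose(2, 1, 0)
    return ImageVolume(voxels=voxels, spacing=img.GetSpacing(),
                       origin=img.GetOrigin(), phase=phase)


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    img = sitk.GetImageFromArray(vol.voxels.transpose(2, 1, 0))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | os.PathLike) -> ROIMask:
    vol = read_volume(path)
    return ROIMask(voxels=vol.voxels > 0.5, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: ROIMask, path: str | os.PathLike) -> None:
    img = sitk.GetImageFromArray(mask.voxels.astype(np.uint8).transpose(2, 1, 0))
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path))


def resample_isotropic(
    vol: ImageVolume,
    mask: ROIMask,
    target: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[ImageVolume, ROIMask]:
    """Resample a volume/mask pair to a uniform target spacing (mm).

    The image is interpolated with a cubic spline; spline overshoot is
    clipped back to the input intensity range.  The mask is resampled with
    nearest-neighbour interpolation to keep it binary.  Already-isotropic
    inputs are returned unchanged.
    """
    target = tuple(float(t) for t in target)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive: {target}")
    if vol.shape != mask.shape:
        raise ValueError(f"volume {vol.shape} and mask {mask.shape} differ in shape")
    if np.allclose(vol.spacing, target, atol=1e-9):
        return vol, mask

    old_shape = np.array(vol.shape)
    old_spacing = np.array(vol.spacing)
    new_shape = np.maximum(1, np.round(old_shape * old_spacing / np.array(target))).astype(int)
    # New voxel j sits at world origin + j*target; sample the spline there.
    axes = [np.arange(n) * t / s for n, t, s in zip(new_shape, target, old_spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    resampled = ndimage.map_coordinates(vol.voxels, coords, order=3, mode="mirror")
    resampled = np.clip(resampled, vol.voxels.min(), vol.voxels.max())
    new_mask = ndimage.map_coordinates(mask.voxels.astype(np.uint8), coords,
                                       order=0, mode="nearest") > 0.5
    if not new_mask.any():
        raise ValueError("mask is empty after resampling (lesion below target resolution)")
    out_vol = ImageVolume(voxels=resampled, spacing=target, origin=vol.origin,
                          phase=vol.phase)
    out_mask = ROIMask(voxels=new_mask, spacing=target, origin=mask.origin)
    return out_vol, out_mask


def extract_roi(
    vol: ImageVolume, mask: ROIMask, pad: int = 1
) -> tuple[ImageVolume, ROIMask]:
    """Crop both grids to the mask bounding box plus ``pad`` voxels.

    The padding is clipped at the grid boundary; the mask foreground is
    preserved exactly.
    """
    if vol.shape != mask.shape:
        raise ValueError(f"volume {vol.shape} and mask {mask.shape} differ in shape")
    if not mask.voxels.any():
        raise ValueError("cannot crop an empty mask")
    slices = []
    lo_index = []
    for axis in range(3):
        proj = mask.voxels.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.where(proj)[0]
        lo = max(int(idx[0]) - pad, 0)
        hi = min(int(idx[-1]) + pad + 1, mask.shape[axis])
        slices.append(slice(lo, hi))
        lo_index.append(lo)
    new_origin = tuple(o + lo * s for o, lo, s in
                       zip(vol.origin, lo_index, vol.spacing))
    crop_vol = ImageVolume(voxels=vol.voxels[tuple(slices)].copy(),
                           spacing=vol.spacing, origin=new_origin, phase=vol.phase)
    crop_mask = ROIMask(voxels=mask.voxels[tuple(slices)].copy(),
                        spacing=mask.spacing, origin=new_origin)
    return crop_vol, crop_mask


def check_coregistered(phases: Sequence[ImageVolume]) -> None:
    """Verify that all phases share grid shape and spacing (registration is
    assumed done upstream)."""
    ref = phases[0]
    for vol in phases[1:]:
        if vol.shape != ref.shape or not np.allclose(vol.spacing, ref.spacing):
            raise ValueError(
                f"phases are not co-registered: {vol.shape}@{vol.spacing} vs "
                f"{ref.shape}@{ref.spacing}")


MANIFEST_COLUMNS = ("case_id", "label", "arterial", "venous", "delayed", "mask")


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    manifest.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return manifest


def load_case(row: pd.Series | dict, base_dir: str | os.PathLike | None = None
              ) -> tuple[dict[str, ImageVolume], ROIMask, int]:
    """Load one manifest row into (phases, mask, label)."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    phases = {ph: read_volume(base / str(row[ph]), phase=ph) for ph in PHASES}
    mask = read_mask(base / str(row["mask"]))
    check_coregistered(list(phases.values()))
    if phases["venous"].shape != mask.shape:
        raise ValueError("mask does not match phase grids")
    return phases, mask, int(row["label"])


def copy_with(vol: ImageVolume, voxels: np.ndarray) -> ImageVolume:
    """A same-geometry volume with replaced voxel data."""
    return replace(vol, voxels=voxels)
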