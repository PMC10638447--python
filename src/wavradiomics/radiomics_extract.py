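"""Radiomics feature extraction in the original and wavelet domains.

Feature-vector arithmetic per contrast phase:

- original domain: 18 first-order + 14 shape + 68 texture = 100 features;
- each wavelet subband: 18 first-order + 68 texture = 86 features
  (shape depends only on the mask and is not recomputed per subband);
- one level, 8 subbands: 8 * 86 = 688 wavelet features per phase.

Three phases therefore yield 300 original-domain features, 2064
wavelet-domain features and 2364 in total for a level-1 decomposition.

Feature names follow the grammar ``{phase}_{domain}_{type}_{name}`` with
domain ``original`` or ``wavelet-LLL`` ... ``wavelet-HHH`` and type one of
``firstorder``, ``shape``, ``glcm``, ``glrlm``, ``glszm``, ``gldm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .io_volumes import (ImageVolume, ROIMask, PHASES, check_coregistered,
                         copy_with, extract_roi, resample_isotropic)
from .texture import QuantizedROI, texture_features, N_TEXTURE_FEATURES
from .wavelet3d import SUBBAND_LABELS, decompose

FIRST_ORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)   # 18

SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)   # 14


@dataclass
class FeatureVector:
    """Ordered feature values with unique qualified names."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return self.values.size

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    @staticmethod
    def concat(parts: Sequence["FeatureVector"]) -> "FeatureVector":
        names = [n for p in parts for n in p.names]
        values = np.concatenate([p.values for p in parts]) if parts else np.empty(0)
        return FeatureVector(names=names, values=values)


@dataclass
class ExtractionConfig:
    """Knobs of the extraction pipeline, recorded next to every table."""

    bin_width: float = 25.0          # HU per gray level
    family: str = "haar"
    level: int = 1
    boundary: str = "periodic"
    domains: tuple[str, ...] = ("original", "wavelet")
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    crop_pad: int = 2                # voxels of context kept around the ROI
    gldm_alpha: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def discretize(vol: ImageVolume | np.ndarray, mask: np.ndarray | ROIMask,
               bin_width: float) -> QuantizedROI:
    """Min-anchored fixed-bin-width discretisation of in-mask intensities.

    ``level(v) = floor((v - min_in_mask) / bin_width) + 1``; adding a
    constant offset to the ROI leaves the levels unchanged.
    """
    voxels = vol.voxels if isinstance(vol, ImageVolume) else np.asarray(vol, float)
    m = mask.voxels if isinstance(mask, ROIMask) else np.asarray(mask, bool)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not m.any():
        raise ValueError("mask is empty")
    inside = voxels[m]
    if not np.all(np.isfinite(inside)):
        raise ValueError("non-finite voxels inside the mask")
    levels = np.zeros(voxels.shape, dtype=np.int64)
    levels[m] = np.floor((inside - inside.min()) / bin_width).astype(np.int64) + 1
    return QuantizedROI(levels=levels, mask=m, ng=int(levels.max()),
                        bin_width=float(bin_width))


def first_order_features(vol: ImageVolume | np.ndarray, mask: np.ndarray | ROIMask,
                         quantized: QuantizedROI,
                         voxel_volume: float = 1.0) -> FeatureVector:
    """The 18-value first-order roster on in-mask intensities."""
    voxels = vol.voxels if isinstance(vol, ImageVolume) else np.asarray(vol, float)
    m = mask.voxels if isinstance(mask, ROIMask) else np.asarray(mask, bool)
    x = voxels[m]
    if x.size == 0:
        raise ValueError("mask is empty")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())                      # population variance
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    # Histogram probabilities from the shared discretisation.
    counts = np.bincount(quantized.levels[m], minlength=quantized.ng + 1)[1:]
    p = counts / n
    pnz = p[p > 0]
    skew = 0.0 if sd == 0 else float(((x - mean) ** 3).mean() / sd ** 3)
    kurt = 0.0 if sd == 0 else float(((x - mean) ** 4).mean() / sd ** 4)
    values = {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(voxel_volume * (x ** 2).sum()),
        "Entropy": float(-(pnz * np.log2(pnz)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p ** 2).sum()),
    }
    return FeatureVector(names=list(FIRST_ORDER_FEATURES),
                         values=np.array([values[k] for k in FIRST_ORDER_FEATURES]))


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass   # degenerate (coplanar/collinear) point sets: brute force
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def shape_features(mask: ROIMask | np.ndarray,
                   spacing: Sequence[float] | None = None) -> FeatureVector:
    """The 14-value mesh-based shape roster.

    Surface area and mesh volume come from a marching-cubes triangulation
    of the (zero-padded) binary mask; axis lengths from a principal-
    component analysis of the physical voxel coordinates.
    """
    if isinstance(mask, ROIMask):
        m, sp = mask.voxels, np.array(mask.spacing)
    else:
        m = np.asarray(mask, bool)
        sp = np.array(spacing if spacing is not None else (1.0, 1.0, 1.0), float)
    if not m.any():
        raise ValueError("mask is empty")
    n = int(m.sum())
    voxel_volume = float(np.prod(sp))

    padded = np.pad(m.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(sp))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->", tri[:, 0],
                                      np.cross(tri[:, 1], tri[:, 2])) / 6.0))

    coords = np.argwhere(m) * sp                      # physical coordinates
    centered = coords - coords.mean(axis=0)
    eigvals = np.sort(np.linalg.eigvalsh(np.cov(centered.T, bias=False)))[::-1] \
        if n > 1 else np.zeros(3)
    eigvals = np.clip(eigvals, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
    flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 1.0

    # Surface voxels only, for diameters.
    from scipy import ndimage as _ndi
    eroded = _ndi.binary_erosion(m)
    boundary = coords[~eroded[m]] if eroded.any() else coords
    max3d = _max_pairwise_distance(boundary)

    def _planar(axis: int) -> float:
        best = 0.0
        idx = np.argwhere(m)
        for val in np.unique(idx[:, axis]):
            plane = idx[idx[:, axis] == val] * sp
            keep = [a for a in range(3) if a != axis]
            best = max(best, _max_pairwise_distance(plane[:, keep]))
        return best

    values = {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": ((36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0)
                       / surface_area) if surface_area > 0 else 0.0,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": _planar(2),     # in-plane (x, y)
        "Maximum2DDiameterColumn": _planar(1),    # (x, z)
        "Maximum2DDiameterRow": _planar(0),       # (y, z)
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
    return FeatureVector(names=list(SHAPE_FEATURES),
                         values=np.array([values[k] for k in SHAPE_FEATURES]))


def _domain_features(voxels: np.ndarray, mask: np.ndarray, config: ExtractionConfig,
                     voxel_volume: float) -> FeatureVector:
    """First-order + texture features of one (phase, domain) image."""
    q = discretize(voxels, mask, config.bin_width)
    fo = first_order_features(voxels, mask, q, voxel_volume=voxel_volume)
    tex_names, tex_values = texture_features(q, alpha=config.gldm_alpha)
    fo_names = [f"firstorder_{n}" for n in fo.names]
    return FeatureVector(names=fo_names + tex_names,
                         values=np.concatenate([fo.values, tex_values]))


def extract_case(phases: Mapping[str, ImageVolume], mask: ROIMask,
                 config: ExtractionConfig | None = None) -> FeatureVector:
    """Extract the full multiphase feature vector for one lesion.

    Each phase is resampled to the target spacing, cropped to the lesion
    bounding box (plus padding for wavelet boundary context), decomposed
    into wavelet subbands, and summarised by the configured rosters.
    """
    config = config or ExtractionConfig()
    missing = [ph for ph in PHASES if ph not in phases]
    if missing:
        raise ValueError(f"missing phases: {missing}")
    check_coregistered([phases[ph] for ph in PHASES])
    voxel_volume = float(np.prod(config.target_spacing))

    parts: list[FeatureVector] = []
    shared_mask: ROIMask | None = None
    for ph in PHASES:
        vol, msk = resample_isotropic(phases[ph], mask, config.target_spacing)
        crop_vol, crop_mask = extract_roi(vol, msk, pad=config.crop_pad)
        if shared_mask is None:
            shared_mask = crop_mask
        if "original" in config.domains:
            dom = _domain_features(crop_vol.voxels, crop_mask.voxels, config,
                                   voxel_volume)
            shp = shape_features(crop_mask)
            parts.append(FeatureVector(
                names=[f"{ph}_original_{n}" for n in dom.names]
                      + [f"{ph}_original_shape_{n}" for n in shp.names],
                values=np.concatenate([dom.values, shp.values])))
        if "wavelet" in config.domains:
            subbands = decompose(crop_vol, family=config.family,
                                 level=config.level, mode=config.boundary)
            for sb in subbands:
                tag = (f"wavelet-{sb.label}" if config.level == 1
                       else f"wavelet{sb.level}-{sb.label}")
                dom = _domain_features(sb.voxels, crop_mask.voxels, config,
                                       voxel_volume)
                parts.append(FeatureVector(
                    names=[f"{ph}_{tag}_{n}" for n in dom.names],
                    values=dom.values))
    return FeatureVector.concat(parts)


def expected_feature_count(config: ExtractionConfig | None = None,
                           n_phases: int = 3) -> int:
    """Closed-form feature count for a configuration (audit helper)."""
    config = config or ExtractionConfig()
    per_phase = 0
    n_fo = len(FIRST_ORDER_FEATURES)
    if "original" in config.domains:
        per_phase += n_fo + len(SHAPE_FEATURES) + N_TEXTURE_FEATURES
    if "wavelet" in config.domains:
        per_phase += 8 * config.level * (n_fo + N_TEXTURE_FEATURES)
    return n_phases * per_phase


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

def build_feature_table(rows: Sequence[FeatureVector], labels: Sequence[int],
                        case_ids: Sequence | None = None) -> pd.DataFrame:
    """Stack per-case vectors into an M x N table with a final label column."""
    if len(rows) != len(labels):
        raise ValueError("rows/labels length mismatch")
    ref = rows[0].names
    for r in rows[1:]:
        if r.names != ref:
            raise ValueError("inconsistent feature names across cases")
    table = pd.DataFrame([r.values for r in rows], columns=ref)
    table["label"] = list(labels)
    if case_ids is not None:
        table.index = pd.Index(case_ids, name="case_id")
    return table


def write_feature_table(table: pd.DataFrame, path, config: ExtractionConfig
                        | None = None) -> None:
    table.to_csv(path, index=table.index.name is not None)
    if config is not None:
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            fh.write(config.to_json())


def read_feature_table(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a table written by :func:`write_feature_table`.

    Returns (full table, labels, feature names).
    """
    table = pd.read_csv(path)
    if "case_id" in table.columns:
        table = table.set_index("case_id")
    if "label" not in table.columns:
        raise ValueError("feature table lacks a 'label' column")
    labels = table["label"].to_numpy(dtype=int)
    names = [c for c in table.columns if c != "label"]
    return table, labels, names


def parse_feature_name(name: str) -> dict[str, str]:
    """Split a qualified name into phase / domain / type / name fields."""
    parts = name.split("_", 2)
    if len(parts) < 3:
        raise ValueError(f"not a qualified feature name: {name!r}")
    phase, domain, rest = parts
    ftype, _, fname = rest.partition("_")
    return {"phase": phase, "domain": domain, "type": ftype, "name": fname}
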