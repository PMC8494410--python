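"""Resampling policy, intensity standardization, and grid restoration.

The working grid is decided once from the first channel's geometry and
shared by all channels and the drawing (they are co-registered). Resampling
is triggered by either of two rules:

* anisotropy — the largest and smallest voxel spacing differ by more than
  a margin (default 0.1 mm);
* size — the grid holds 10 million voxels or more.

When triggered, every image is resampled to one isotropic spacing: the
smallest value, at least the smallest original spacing, that brings the
voxel count strictly under the cap. Intensities are interpolated linearly,
label drawings nearest-neighbor, and results are always resampled back to
the original grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .geometry import ImageGeometry
from .imageio import LabelDrawing, from_sitk, to_sitk

DEFAULT_ANISOTROPY_MARGIN_MM = 0.1
DEFAULT_VOXEL_CAP = 10_000_000


@dataclass(frozen=True)
class PreprocessConfig:
    anisotropy_margin_mm: float = DEFAULT_ANISOTROPY_MARGIN_MM
    voxel_cap: int = DEFAULT_VOXEL_CAP

    def __post_init__(self):
        if self.anisotropy_margin_mm < 0:
            raise ValueError("anisotropy_margin_mm must be >= 0")
        if self.voxel_cap < 1:
            raise ValueError("voxel_cap must be >= 1")


@dataclass(frozen=True)
class ResamplePlan:
    resample_needed: bool
    target_spacing_mm: float
    original_geometry: ImageGeometry


def resampled_size(geometry: ImageGeometry, s: float) -> tuple[int, ...]:
    """New grid size at isotropic spacing s: round(size·spacing/s), min 1."""
    return tuple(
        max(1, int(round(sz * sp / s)))
        for sz, sp in zip(geometry.size, geometry.spacing)
    )


def needs_resampling(geometry: ImageGeometry, cfg: PreprocessConfig) -> bool:
    """True iff spacing anisotropy exceeds the margin or the grid is too big.

    Anisotropy uses a strict comparison: spacings *more than* the margin
    apart trigger resampling. The voxel cap is strict as well: a grid of
    exactly ``voxel_cap`` voxels is resampled.
    """
    spacing = geometry.spacing
    # 1e-9 guard so header values intended to sit exactly at the margin
    # (e.g. 1.1 - 1.0) are not pushed over it by float representation
    if (max(spacing) - min(spacing)) > cfg.anisotropy_margin_mm + 1e-9:
        return True
    return geometry.voxel_count >= cfg.voxel_cap


def target_isotropic_spacing(geometry: ImageGeometry,
                             cfg: PreprocessConfig) -> float:
    """Smallest isotropic spacing >= min original spacing under the cap.

    Seeded with the closed-form estimate (prod of physical extents /
    cap)^(1/D), then stepped upward in 0.01 mm increments until the
    resampled voxel count drops below the cap. Never returns less than the
    smallest original spacing.
    """
    s_min = min(geometry.spacing)
    extent = float(np.prod([sz * sp for sz, sp in
                            zip(geometry.size, geometry.spacing)]))
    seed = (extent / cfg.voxel_cap) ** (1.0 / geometry.ndim)
    step = 0.01
    # Jump to the step-grid point just below the closed-form estimate (the
    # grid is anchored at s_min, so a larger cap can never yield a larger
    # spacing), then walk upward until the count predicate holds.
    n = max(0, int(np.floor((seed - s_min) / step)) - 1)
    s = s_min + n * step
    while int(np.prod(resampled_size(geometry, s))) >= cfg.voxel_cap:
        s += step
    return float(s)


def plan_resampling(geometry: ImageGeometry,
                    cfg: PreprocessConfig) -> ResamplePlan:
    if not needs_resampling(geometry, cfg):
        return ResamplePlan(False, min(geometry.spacing), geometry)
    return ResamplePlan(True, target_isotropic_spacing(geometry, cfg), geometry)


def _resample(array: np.ndarray, geometry: ImageGeometry, s: float,
              interpolator) -> tuple[np.ndarray, ImageGeometry]:
    new_size = resampled_size(geometry, s)
    img = to_sitk(array, geometry)
    out = sitk.Resample(
        img,
        size=tuple(reversed(new_size)),
        transform=sitk.Transform(),
        interpolator=interpolator,
        outputOrigin=img.GetOrigin(),
        outputSpacing=tuple([float(s)] * geometry.ndim),
        outputDirection=img.GetDirection(),
        defaultPixelValue=0.0,
        outputPixelType=img.GetPixelID(),
        useNearestNeighborExtrapolator=True,
    )
    return from_sitk(out)


def resample_channel(channel: np.ndarray, geometry: ImageGeometry,
                     s: float) -> tuple[np.ndarray, ImageGeometry]:
    """Linearly resample one intensity channel to isotropic spacing s."""
    if s <= 0:
        raise ValueError("target spacing must be > 0")
    arr, geom = _resample(channel.astype(np.float64), geometry, s,
                          sitk.sitkLinear)
    return arr, geom


def resample_labels(drawing: LabelDrawing, s: float) -> LabelDrawing:
    """Nearest-neighbor resample of a label drawing; introduces no new labels."""
    if s <= 0:
        raise ValueError("target spacing must be > 0")
    arr, geom = _resample(drawing.labels.astype(np.int32), drawing.geometry,
                          s, sitk.sitkNearestNeighbor)
    return LabelDrawing(labels=arr.astype(np.int32), geometry=geom)


def standardize(channel: np.ndarray) -> np.ndarray:
    """Shift/scale to zero mean, unit population standard deviation.

    A constant channel (zero variance) maps to all zeros.
    """
    arr = np.asarray(channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot standardize an empty channel")
    mean = arr.mean()
    std = arr.std()  # population (÷N)
    if std == 0.0:
        return np.zeros_like(arr)
    return (arr - mean) / std


def restore_to_original(pred: np.ndarray, working: ImageGeometry,
                        original: ImageGeometry) -> np.ndarray:
    """Nearest-neighbor resample of a predicted label image back to the
    original grid. Identity when the grids already match."""
    if working.matches(original):
        return pred.astype(np.int32)
    img = to_sitk(pred.astype(np.int32), working)
    out = sitk.Resample(
        img,
        size=tuple(reversed(original.size)),
        transform=sitk.Transform(),
        interpolator=sitk.sitkNearestNeighbor,
        outputOrigin=tuple(reversed(original.origin)),
        outputSpacing=tuple(reversed(original.spacing)),
        outputDirection=original.direction,
        defaultPixelValue=0,
        outputPixelType=img.GetPixelID(),
        useNearestNeighborExtrapolator=True,
    )
    arr, _ = from_sitk(out)
    return arr.astype(np.int32)
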