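"""Segmentation evaluation: Dice overlap, volumes, volume correlation."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ImlsegError, InputError
from .geometry import ImageGeometry


def dice(a: np.ndarray, b: np.ndarray, label: int) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) for one label.

    Defined as 1.0 when the label is absent from both images (perfect
    agreement on absence).
    """
    if a.shape != b.shape:
        raise InputError("label images must share a grid")
    ma = a == label
    mb = b == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def merged_foreground_dice(a: np.ndarray, b: np.ndarray,
                           labels: set[int] | list[int]) -> float:
    """Dice of the union of the listed labels (the "whole structure")."""
    if a.shape != b.shape:
        raise InputError("label images must share a grid")
    labels = list(labels)
    ma = np.isin(a, labels)
    mb = np.isin(b, labels)
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def volume_ml(mask: np.ndarray, geometry: ImageGeometry) -> float:
    """Physical volume of a boolean mask in milliliters."""
    return float(np.count_nonzero(mask)) * geometry.voxel_volume_mm3 / 1000.0


def pearson_r(xs, ys) -> float:
    """Pearson product-moment correlation of paired values."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise InputError("inputs must be equal-length 1D sequences")
    if len(xs) < 2:
        raise InputError("correlation requires at least 2 pairs")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ImlsegError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(xs, ys).statistic)


def overlap_report(a: np.ndarray, b: np.ndarray, geometry: ImageGeometry,
                   labels: list[int] | None = None) -> dict:
    """Per-label Dice and volumes plus the merged-foreground Dice."""
    if labels is None:
        present = np.union1d(np.unique(a), np.unique(b))
        labels = [int(v) for v in present if v != 0]
    report = {
        "per_label": {
            int(k): {
                "dice": dice(a, b, k),
                "volume_a_ml": volume_ml(a == k, geometry),
                "volume_b_ml": volume_ml(b == k, geometry),
            } for k in labels
        },
        "merged_foreground_dice": merged_foreground_dice(a, b, labels),
    }
    return report
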