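"""Per-voxel feature vectors and the capped, balanced training set.

Each voxel is described by F = C + C*L + D features, in this fixed column
order:

1. the C standardized channel intensities, in input channel order;
2. the C*L normalized geodesic distances, channel-major then label-minor
   (all labels of channel 0, then all labels of channel 1, ...);
3. the D coordinate maps — the voxel's integer index along each array
   dimension, in dimension order.

Only drawn voxels become training rows. When the drawing holds more than
``max_samples`` voxels (default 3000) a class-balanced subset is drawn:
per-class quotas follow largest-remainder apportionment of the class
fractions, and rows within a class are picked uniformly at random under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agd import AGDStack
from .errors import InsufficientLabelsError
from .geometry import ImageGeometry
from .imageio import LabelDrawing, MultiChannelImage

DEFAULT_MAX_SAMPLES = 3000


@dataclass(frozen=True)
class TrainingSet:
    """Feature rows for drawn voxels only."""

    X: np.ndarray  # (n_rows, F)
    y: np.ndarray  # (n_rows,)

    @property
    def class_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.y, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature min/max learned from training rows (min-max to [0,1])."""

    minimum: np.ndarray
    maximum: np.ndarray


def coordinate_maps(geometry: ImageGeometry) -> list[np.ndarray]:
    """One map per dimension holding each voxel's integer index (0..size-1)."""
    grids = np.meshgrid(*[np.arange(s) for s in geometry.size], indexing="ij")
    return [g.astype(np.float64) for g in grids]


def feature_stack(image: MultiChannelImage, agd: AGDStack) -> np.ndarray:
    """(n_voxels, F) feature matrix in lexicographic voxel order."""
    if agd.maps.shape[2:] != image.geometry.size:
        raise ValueError("geodesic stack grid does not match image grid")
    cols = [ch.ravel() for ch in image.channels]
    C, L = agd.n_channels, agd.n_labels
    for ci in range(C):
        for li in range(L):
            cols.append(agd.maps[ci, li].ravel())
    cols.extend(m.ravel() for m in coordinate_maps(image.geometry))
    return np.column_stack(cols)


def training_samples(stack: np.ndarray, drawing: LabelDrawing) -> TrainingSet:
    """Rows of the feature stack at drawn (nonzero) voxels."""
    flat = drawing.labels.ravel()
    mask = flat != 0
    y = flat[mask]
    if len(np.unique(y)) < 2:
        raise InsufficientLabelsError(
            "training requires at least 2 classes of drawn voxels")
    return TrainingSet(X=stack[mask], y=y.astype(np.int64))


def _largest_remainder_quotas(counts: np.ndarray, cap: int) -> np.ndarray:
    """Apportion ``cap`` rows across classes proportionally.

    Every class keeps at least one row; ties in the fractional remainders
    are broken toward lower class index (i.e. lower class id, since counts
    are given in sorted-id order).
    """
    fractions = counts / counts.sum()
    ideal = fractions * cap
    quotas = np.floor(ideal).astype(np.int64)
    quotas = np.maximum(quotas, 1)
    remainder = cap - quotas.sum()
    if remainder > 0:
        order = np.lexsort((np.arange(len(counts)), -(ideal - np.floor(ideal))))
        for i in range(remainder):
            quotas[order[i % len(counts)]] += 1
    elif remainder < 0:
        # over-allocated by the >=1 floor: trim from the largest quotas
        order = np.argsort(-quotas, kind="stable")
        i = 0
        while remainder < 0:
            j = order[i % len(counts)]
            if quotas[j] > 1:
                quotas[j] -= 1
                remainder += 1
            i += 1
    quotas = np.minimum(quotas, counts)
    return quotas


def balanced_subsample(ts: TrainingSet, cap: int = DEFAULT_MAX_SAMPLES,
                       seed: int = 42) -> TrainingSet:
    """Cap the training set while retaining per-class ratios.

    Identity when the row count is already within the cap. Deterministic
    for a fixed seed.
    """
    n = ts.X.shape[0]
    class_ids, counts = np.unique(ts.y, return_counts=True)
    if cap < len(class_ids):
        raise ValueError("cap must be at least the number of classes")
    if n <= cap:
        return ts
    quotas = _largest_remainder_quotas(counts, cap)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cid, quota in zip(class_ids, quotas):
        rows = np.flatnonzero(ts.y == cid)
        keep.append(rng.choice(rows, size=int(quota), replace=False))
    idx = np.sort(np.concatenate(keep))
    return TrainingSet(X=ts.X[idx], y=ts.y[idx])


def fit_scaling(train_rows: np.ndarray) -> ScalingParams:
    if train_rows.shape[0] == 0:
        raise ValueError("cannot fit scaling on zero rows")
    return ScalingParams(minimum=train_rows.min(axis=0),
                         maximum=train_rows.max(axis=0))


def apply_scaling(rows: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Map each feature to [0, 1]; constant features map to 0; values
    outside the training range are clipped.

    The [0, 1] domain is required by the chi-squared and histogram
    intersection kernels, which are defined on nonnegative inputs.
    """
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = (rows - params.minimum) / safe
    scaled[:, span == 0] = 0.0
    return np.clip(scaled, 0.0, 1.0)


def fit_and_apply_scaling(train_rows: np.ndarray, all_rows: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, ScalingParams]:
    params = fit_scaling(train_rows)
    return (apply_scaling(train_rows, params),
            apply_scaling(all_rows, params), params)
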