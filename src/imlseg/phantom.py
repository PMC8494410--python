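"""Synthetic multi-channel phantoms with ground truth and scribbles.

The phantom emulates the structure the segmentation method exploits in real
multiparametric scans: each tissue class has a distinct mean intensity in
at least one channel, corrupted by additive Gaussian noise. Foreground
classes are spheres/ellipsoids on a background; class ids run 1..n_classes
with the background taking the largest id (matching the pipeline's default
background convention).

Scribbles are random-walk strokes dilated to a thickness and clipped
strictly inside the class region, emulating the quick rough drawings a
user makes rather than uniformly sampled voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from .errors import InputError, MissingClassError
from .geometry import ImageGeometry
from .imageio import LabelDrawing, MultiChannelImage

#: Default per-class, per-channel mean intensities for the 3-class,
#: 2-channel phantom: each class is 1.0 away from every other class in at
#: least one channel. At the default noise_sd of 0.15 that separation is
#: about 6.7 noise standard deviations, which keeps the classes recoverable
#: by nearest-mean thresholding at better than 99% accuracy — the property
#: that makes the phantom a valid ground truth for end-to-end checks.
DEFAULT_CLASS_MEANS = ((1.0, 0.0), (0.0, 1.0), (0.0, 0.0))
DEFAULT_NOISE_SD = 0.15

# Fractional centers for successive foreground shapes, chosen so the
# default radii never overlap.
_CENTER_FRACTIONS = ((0.35, 0.35, 0.35), (0.68, 0.68, 0.62),
                     (0.3, 0.7, 0.5), (0.7, 0.3, 0.5))
_RADIUS_FRACTION = 0.16


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, ...] = (48, 64, 64)
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    n_classes: int = 3  # including background
    class_means: tuple[tuple[float, ...], ...] = DEFAULT_CLASS_MEANS
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 42

    def __post_init__(self):
        if any(s < 1 for s in self.size):
            raise InputError("phantom size entries must be >= 1")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if len(self.class_means) != self.n_classes:
            raise InputError("class_means must have one row per class")
        n_ch = {len(m) for m in self.class_means}
        if len(n_ch) != 1:
            raise InputError("class_means rows must have equal length")
        if self.n_classes < 2:
            raise InputError("at least 2 classes (1 ROI + background) needed")
        means = np.asarray(self.class_means, dtype=float)
        for i, j in product(range(self.n_classes), repeat=2):
            if i < j and np.max(np.abs(means[i] - means[j])) == 0:
                raise InputError(
                    f"classes {i + 1} and {j + 1} have identical means in "
                    "every channel")

    @property
    def n_channels(self) -> int:
        return len(self.class_means[0])


def make_phantom(spec: PhantomSpec = PhantomSpec()
                 ) -> tuple[MultiChannelImage, LabelDrawing]:
    """Build the phantom image and its fully-labeled ground truth.

    Foreground classes 1..n_classes-1 are ellipsoids; the background class
    (id n_classes) fills the rest. Deterministic per seed.
    """
    geom = ImageGeometry(size=spec.size, spacing=spec.spacing,
                         origin=(0.0,) * len(spec.size))
    coords = np.meshgrid(*[np.arange(s) * sp for s, sp in
                           zip(spec.size, spec.spacing)], indexing="ij")
    extent = [s * sp for s, sp in zip(spec.size, spec.spacing)]
    radius = _RADIUS_FRACTION * min(extent)

    n_fg = spec.n_classes - 1
    if n_fg > len(_CENTER_FRACTIONS):
        raise InputError(
            f"at most {len(_CENTER_FRACTIONS) + 1} classes supported")
    truth = np.full(spec.size, spec.n_classes, dtype=np.int32)
    for k in range(n_fg):
        fr = _CENTER_FRACTIONS[k][:len(spec.size)]
        center = [f * e for f, e in zip(fr, extent)]
        r2 = sum(((c - mu) / radius) ** 2 for c, mu in zip(coords, center))
        truth[r2 <= 1.0] = k + 1

    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.class_means, dtype=float)
    channels = []
    for ch in range(spec.n_channels):
        mean_map = means[truth - 1, ch]
        noise = rng.normal(0.0, spec.noise_sd, size=spec.size)
        channels.append(mean_map + noise)
    image = MultiChannelImage(channels=tuple(channels), geometry=geom)
    return image, LabelDrawing(labels=truth, geometry=geom)


def _ball(ndim: int, radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1,) * ndim, dtype=bool)
    grids = np.meshgrid(*[np.arange(-radius, radius + 1)] * ndim,
                        indexing="ij")
    return sum(g ** 2 for g in grids) <= radius ** 2


def make_scribbles(truth: LabelDrawing, fraction: float = 0.01,
                   thickness: int = 1, seed: int = 42) -> LabelDrawing:
    """Random-walk strokes inside each class, covering ~``fraction`` of it.

    Strokes are painted with a ball of the given thickness and clipped to a
    one-voxel-eroded class mask, so no scribble voxel touches another
    class's region (full-neighborhood adjacency). ``fraction`` of 1 returns
    the full truth.
    """
    if not 0 < fraction <= 1:
        raise InputError("fraction must be in (0, 1]")
    if fraction >= 1.0:
        return LabelDrawing(labels=truth.labels.copy(),
                            geometry=truth.geometry)
    ndim = truth.geometry.ndim
    rng = np.random.default_rng(seed)
    offsets = np.array([o for o in product((-1, 0, 1), repeat=ndim)
                        if any(o)], dtype=np.int64)
    brush = _ball(ndim, (thickness - 1) // 2)
    scribbles = np.zeros_like(truth.labels)
    shape = np.array(truth.labels.shape)
    for cid in truth.class_ids:
        mask = truth.labels == cid
        interior = ndimage.binary_erosion(
            mask, structure=np.ones((3,) * ndim, dtype=bool), border_value=1)
        if not interior.any():
            raise MissingClassError(
                cid, f"class {cid} too small to hold an interior stroke")
        target = max(1, int(round(fraction * mask.sum())))
        target = min(target, int(interior.sum()))
        painted = np.zeros_like(mask)
        candidates = np.argwhere(interior)
        pos = candidates[rng.integers(len(candidates))]
        # The stroke heads toward successive random waypoints so it sweeps
        # across the whole class region the way a quick user drawing does,
        # instead of wandering locally.
        waypoint = candidates[rng.integers(len(candidates))]
        n_painted = 0
        steps = 0
        max_steps = 200 * target + 1000
        while n_painted < target and steps < max_steps:
            steps += 1
            n_painted += _paint(painted, interior, pos, brush)
            if np.all(pos == waypoint) or steps % 200 == 0:
                waypoint = candidates[rng.integers(len(candidates))]
            delta = np.sign(waypoint - pos)
            jitter = rng.random(ndim) < 0.25
            delta[jitter] = rng.integers(-1, 2, size=int(jitter.sum()))
            nxt = pos + delta
            inb = np.all((nxt >= 0) & (nxt < shape))
            if not inb or not interior[tuple(nxt)]:
                moves = pos + offsets
                valid = moves[np.all((moves >= 0) & (moves < shape), axis=1)]
                valid = valid[interior[tuple(valid.T)]]
                if len(valid) == 0:
                    pos = candidates[rng.integers(len(candidates))]
                    continue
                nxt = valid[rng.integers(len(valid))]
            pos = nxt
        if n_painted < target:  # safety net for labyrinthine regions
            unpainted = candidates[~painted[tuple(candidates.T)]]
            extra = unpainted[rng.permutation(len(unpainted))[:target - n_painted]]
            painted[tuple(extra.T)] = True
        scribbles[painted] = cid
    return LabelDrawing(labels=scribbles, geometry=truth.geometry)


def _paint(painted: np.ndarray, allowed: np.ndarray, pos: np.ndarray,
           brush: np.ndarray) -> int:
    """Stamp the brush at pos, clipped to ``allowed``; return voxels added."""
    r = (np.array(brush.shape) - 1) // 2
    lo = np.maximum(pos - r, 0)
    hi = np.minimum(pos + r + 1, painted.shape)
    blo = lo - (pos - r)
    bhi = blo + (hi - lo)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    bsl = tuple(slice(a, b) for a, b in zip(blo, bhi))
    stamp = brush[bsl] & allowed[sl]
    added = int((stamp & ~painted[sl]).sum())
    painted[sl] |= stamp
    return added


def make_corrective_scribbles(truth: LabelDrawing, predicted: np.ndarray,
                              background_id: int | None = None,
                              min_error_size: int = 20,
                              reinforce_fraction: float = 0.01,
                              seed: int = 43) -> LabelDrawing:
    """Emulate a user's correction round after inspecting a segmentation.

    Two ingredients, mirroring what a user actually does on the second
    pass:

    * corrections — connected components of disagreement between
      ``predicted`` and the truth (full-neighborhood connectivity) of at
      least ``min_error_size`` voxels, the "representative misclassified
      areas" a user would notice, each painted over its interior with the
      true label; scattered boundary-voxel disagreements are ignored, as a
      user would ignore them;
    * reinforcement — a fresh round of scribble strokes over every class
      at ``reinforce_fraction`` coverage (0 disables it). Without it,
      classes the model already segments well receive no new evidence
      while the corrected areas flood the training set, and their
      boundaries can drift on retraining.

    Correction strokes win where the two overlap. ``predicted`` may have
    the background class mapped to 0 (the pipeline's default output); pass
    ``background_id`` so truth background compares equal to predicted 0.
    """
    if background_id is None:
        background_id = max(truth.class_ids)
    truth_cmp = np.where(truth.labels == background_id, 0, truth.labels)
    pred_cmp = np.where(predicted == background_id, 0, predicted)
    error = pred_cmp != truth_cmp
    ndim = truth.geometry.ndim
    struct = np.ones((3,) * ndim, dtype=bool)
    comp_labels, n = ndimage.label(error, structure=struct)
    add = np.zeros_like(truth.labels)
    for ci in range(1, n + 1):
        comp = comp_labels == ci
        if comp.sum() < min_error_size:
            continue
        ids, counts = np.unique(truth.labels[comp], return_counts=True)
        cid = int(ids[np.argmax(counts)])
        region = comp & (truth.labels == cid)
        interior = ndimage.binary_erosion(region, structure=struct,
                                          border_value=0)
        add[interior if interior.any() else region] = cid
    if reinforce_fraction > 0:
        extra = make_scribbles(truth, fraction=reinforce_fraction, seed=seed)
        add = np.where(add != 0, add, extra.labels)
    return LabelDrawing(labels=add.astype(np.int32), geometry=truth.geometry)


def make_anisotropic_variant(image: MultiChannelImage,
                             spacing: tuple[float, ...]) -> MultiChannelImage:
    """Same voxel data under an altered header spacing (exercises the
    resampling rules without touching intensities)."""
    if any(s <= 0 for s in spacing):
        raise InputError("spacing must be positive")
    geom = ImageGeometry(size=image.geometry.size, spacing=spacing,
                         origin=image.geometry.origin,
                         direction=image.geometry.direction)
    return MultiChannelImage(channels=image.channels, geometry=geom)
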