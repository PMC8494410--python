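"""End-to-end segmentation pipeline and the iterative refine loop.

Stages, in order: resampling plan (anisotropy margin / voxel cap) ->
channel and label resampling -> intensity standardization -> geodesic
distance stack -> feature assembly -> training rows -> balanced cap ->
min-max scaling -> three-kernel SVM ensemble training -> whole-volume
voted prediction -> restoration to the original grid -> optional zeroing
of the background class.

Refinement is stateless: corrective scribbles are merged over the previous
drawing (new strokes win on conflicts) and the whole pipeline re-runs, so
identical inputs and seed always reproduce identical results.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .agd import AGDParams, all_agd_maps
from .ensemble import CVGrid, train_ensemble, predict_volume
from .errors import (
    CoRegistrationError,
    ImlsegError,
    InsufficientLabelsError,
    MissingClassError,
)
from .features import (
    DEFAULT_MAX_SAMPLES,
    balanced_subsample,
    feature_stack,
    fit_scaling,
    apply_scaling,
    training_samples,
)
from .geometry import ImageGeometry
from .imageio import LabelDrawing, MultiChannelImage
from .preprocess import (
    PreprocessConfig,
    plan_resampling,
    resample_channel,
    resample_labels,
    restore_to_original,
    standardize,
)


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    agd: AGDParams = field(default_factory=AGDParams)
    grid: CVGrid = field(default_factory=CVGrid)
    max_samples: int = DEFAULT_MAX_SAMPLES
    seed: int = 42
    background_label_id: int | None = None  # None -> largest class id
    emit_background: bool = False

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        """Build from a flat key-value mapping (the config-file format)."""
        d = dict(d)
        pp = PreprocessConfig(
            anisotropy_margin_mm=float(d.pop("anisotropy_margin_mm", 0.1)),
            voxel_cap=int(d.pop("voxel_cap", 10_000_000)))
        agd = AGDParams(
            intensity_weight=float(d.pop("intensity_weight", 1.0)),
            max_passes=int(d.pop("max_passes", 4)))
        grid = CVGrid(
            c_values=tuple(float(c) for c in d.pop("c_grid", CVGrid().c_values)),
            gamma_values=tuple(float(g) for g in
                               d.pop("gamma_grid", CVGrid().gamma_values)),
            folds=int(d.pop("cv_folds", CVGrid().folds)))
        cfg = cls(
            preprocess=pp, agd=agd, grid=grid,
            max_samples=int(d.pop("max_samples", DEFAULT_MAX_SAMPLES)),
            seed=int(d.pop("seed", 42)),
            background_label_id=(
                None if d.get("background_label_id") is None
                else int(d.pop("background_label_id"))),
            emit_background=bool(d.pop("emit_background", False)))
        d.pop("background_label_id", None)
        if d:
            raise ImlsegError(f"unknown config keys: {sorted(d)}")
        return cfg


@dataclass
class SegmentationResult:
    """Predicted label image on the ORIGINAL input grid."""

    labels: np.ndarray
    geometry: ImageGeometry
    class_counts: dict[int, int]
    provenance: dict[str, Any]


class _Timer:
    def __init__(self):
        self.timings: dict[str, float] = {}
        self._stage = None
        self._t0 = 0.0

    def stage(self, name: str):
        self._stage, self._t0 = name, time.perf_counter()
        return self

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timings[self._stage] = time.perf_counter() - self._t0
        if isinstance(exc, ImlsegError):
            exc.add_note(f"pipeline stage: {self._stage}")
        return False


def segment(images: MultiChannelImage, drawing: LabelDrawing,
            cfg: PipelineConfig = PipelineConfig()) -> SegmentationResult:
    """Segment the whole scan from a sparse label drawing.

    Returns a label image restored to the original grid. Unless
    ``cfg.emit_background`` is set, the background class (by default the
    largest class id in the drawing) is mapped to 0 on output.
    """
    if not images.geometry.matches(drawing.geometry):
        raise CoRegistrationError("drawing is not on the image grid")
    class_ids = drawing.class_ids
    if len(class_ids) < 2:
        raise InsufficientLabelsError(
            "drawing must contain at least 2 distinct nonzero labels")

    original = images.geometry
    timer = _Timer()

    with timer.stage("resample_plan"):
        plan = plan_resampling(original, cfg.preprocess)
    with timer.stage("resample"):
        if plan.resample_needed:
            s = plan.target_spacing_mm
            resampled = [resample_channel(ch, original, s)
                         for ch in images.channels]
            geom = resampled[0][1]
            channels = [arr for arr, _ in resampled]
            work_drawing = resample_labels(drawing, s)
            for cid in class_ids:
                if not (work_drawing.labels == cid).any():
                    raise MissingClassError(
                        cid, f"class {cid} vanished during resampling; "
                        "draw a thicker stroke for it")
        else:
            geom = original
            channels = list(images.channels)
            work_drawing = drawing
    with timer.stage("standardize"):
        channels = [standardize(ch) for ch in channels]
        work_image = MultiChannelImage(channels=tuple(channels), geometry=geom)
    with timer.stage("agd"):
        agd_stack = all_agd_maps(work_image, work_drawing, cfg.agd)
    with timer.stage("features"):
        stack = feature_stack(work_image, agd_stack)
        train = training_samples(stack, work_drawing)
        train = balanced_subsample(train, cap=cfg.max_samples, seed=cfg.seed)
        scaling = fit_scaling(train.X)
        X_train = apply_scaling(train.X, scaling)
        X_all = apply_scaling(stack, scaling)
    with timer.stage("train"):
        model = train_ensemble(X_train, train.y, scaling, cfg.grid, cfg.seed)
    with timer.stage("predict"):
        pred = predict_volume(model, X_all).reshape(geom.size)
    with timer.stage("restore"):
        pred = restore_to_original(pred, geom, original)
        if not cfg.emit_background:
            bg = (cfg.background_label_id if cfg.background_label_id
                  is not None else max(class_ids))
            pred = np.where(pred == bg, 0, pred).astype(np.int32)

    ids, counts = np.unique(pred, return_counts=True)
    provenance = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "resampled": plan.resample_needed,
        "working_spacing_mm": plan.target_spacing_mm,
        "working_size": geom.size,
        "hyperparameters": {
            m.kind: {"C": m.C, "gamma": m.gamma, "cv_accuracy": m.cv_accuracy}
            for m in model.models},
        "timings_s": timer.timings,
    }
    return SegmentationResult(
        labels=pred, geometry=original,
        class_counts={int(i): int(c) for i, c in zip(ids, counts)},
        provenance=provenance)


def merge_drawings(previous: LabelDrawing,
                   additional: LabelDrawing) -> LabelDrawing:
    """Union of two drawings; the additional drawing wins on conflicts."""
    if not previous.geometry.matches(additional.geometry):
        raise CoRegistrationError("drawings are not on the same grid")
    merged = np.where(additional.labels != 0, additional.labels,
                      previous.labels).astype(np.int32)
    return LabelDrawing(labels=merged, geometry=previous.geometry)


def refine(images: MultiChannelImage, previous_drawing: LabelDrawing,
           additional_drawing: LabelDrawing,
           cfg: PipelineConfig = PipelineConfig()) -> SegmentationResult:
    """One correction iteration: merge the corrective strokes over the
    previous drawing and retrain from scratch (stateless)."""
    merged = merge_drawings(previous_drawing, additional_drawing)
    return segment(images, merged, cfg)
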