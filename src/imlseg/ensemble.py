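"""Three-kernel SVM ensemble: cross-validated training and voted prediction.

Three support-vector classifiers — RBF, chi-squared, and histogram
intersection kernels — are trained on the identical scaled training rows.
Hyperparameters come from a stratified k-fold grid search (C and, where the
kernel has one, gamma); ties are broken toward smaller C, then smaller
gamma. Each voxel's final label is the majority of the three model votes;
a three-way disagreement defers to the RBF model.

The SVC solver sees only precomputed Gram matrices, so all three kernels
share one code path; multiclass is one-vs-one (libsvm's default vote
counting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import kernels
from .features import ScalingParams

DEFAULT_C_GRID = (0.1, 0.5, 2.5, 12.5, 62.5, 312.5, 1562.5)
DEFAULT_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
DEFAULT_FOLDS = 5

PREDICT_CHUNK_ROWS = 8192


@dataclass(frozen=True)
class CVGrid:
    c_values: tuple[float, ...] = DEFAULT_C_GRID
    gamma_values: tuple[float, ...] = DEFAULT_GAMMA_GRID
    folds: int = DEFAULT_FOLDS

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.c_values or not self.gamma_values:
            raise ValueError("hyperparameter grids must be nonempty")
        if any(c <= 0 for c in self.c_values):
            raise ValueError("C values must be positive")
        if any(g <= 0 for g in self.gamma_values):
            raise ValueError("gamma values must be positive")


@dataclass
class SVMModel:
    """One trained kernel SVM plus what is needed to evaluate it later."""

    kind: str
    C: float
    gamma: float  # ignored by hist_intersection
    svc: SVC
    train_rows: np.ndarray
    cv_accuracy: float

    @property
    def classes(self) -> np.ndarray:
        return self.svc.classes_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict labels for scaled feature rows, chunked to bound memory."""
        out = np.empty(X.shape[0], dtype=np.int64)
        for start in range(0, X.shape[0], PREDICT_CHUNK_ROWS):
            chunk = X[start:start + PREDICT_CHUNK_ROWS]
            K = kernels.gram(self.kind, chunk, self.train_rows, self.gamma)
            out[start:start + PREDICT_CHUNK_ROWS] = self.svc.predict(K)
        return out


@dataclass
class EnsembleModel:
    rbf_model: SVMModel
    chi2_model: SVMModel
    hist_model: SVMModel
    scaling: ScalingParams
    class_ids: tuple[int, ...] = field(default=())

    @property
    def models(self) -> tuple[SVMModel, SVMModel, SVMModel]:
        return (self.rbf_model, self.chi2_model, self.hist_model)


def _effective_folds(y: np.ndarray, folds: int) -> int:
    min_count = int(np.unique(y, return_counts=True)[1].min())
    if min_count < folds:
        eff = max(2, min_count)
        warnings.warn(
            f"smallest class has {min_count} samples; reducing CV folds "
            f"from {folds} to {eff}", stacklevel=3)
        return eff
    return folds


def _cv_accuracy(K: np.ndarray, y: np.ndarray, C: float, folds: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    scores = []
    for tr, te in skf.split(K, y):
        svc = SVC(kernel="precomputed", C=C)
        svc.fit(K[np.ix_(tr, tr)], y[tr])
        pred = svc.predict(K[np.ix_(te, tr)])
        scores.append(float(np.mean(pred == y[te])))
    return float(np.mean(scores))


def train_svm(X: np.ndarray, y: np.ndarray, kind: str,
              grid: CVGrid = CVGrid(), seed: int = 42) -> SVMModel:
    """Grid-search (C[, gamma]) by stratified k-fold CV accuracy and refit.

    The search is exhaustive over the grid; ties prefer smaller C, then
    smaller gamma. The histogram intersection kernel has no gamma, so its
    search runs over C only. Deterministic for fixed inputs (folds are
    unshuffled; the seed is accepted for interface symmetry).
    """
    if kind not in kernels.KERNEL_KINDS:
        raise ValueError(f"unknown kernel kind {kind!r}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    folds = _effective_folds(y, grid.folds)
    gammas = (1.0,) if kind == "hist_intersection" else grid.gamma_values
    results: list[tuple[float, float, float]] = []  # (acc, C, gamma)
    for gamma in gammas:
        K = kernels.gram(kind, X, X, gamma)
        for C in grid.c_values:
            results.append((_cv_accuracy(K, y, C, folds), C, gamma))
    best_acc = max(r[0] for r in results)
    _, best_C, best_gamma = min(
        (r for r in results if r[0] == best_acc), key=lambda r: (r[1], r[2]))
    K = kernels.gram(kind, X, X, best_gamma)
    svc = SVC(kernel="precomputed", C=best_C)
    svc.fit(K, y)
    return SVMModel(kind=kind, C=best_C, gamma=best_gamma, svc=svc,
                    train_rows=np.ascontiguousarray(X, dtype=np.float64),
                    cv_accuracy=best_acc)


def train_ensemble(X: np.ndarray, y: np.ndarray, scaling: ScalingParams,
                   grid: CVGrid = CVGrid(), seed: int = 42) -> EnsembleModel:
    """Train the three kernel models on identical rows and labels.

    The three trainings are mutually independent, so sequential and
    concurrent execution give identical models for a fixed seed.
    """
    rbf = train_svm(X, y, "rbf", grid, seed)
    chi2 = train_svm(X, y, "chi2", grid, seed)
    hist = train_svm(X, y, "hist_intersection", grid, seed)
    class_ids = tuple(int(c) for c in np.unique(y))
    return EnsembleModel(rbf_model=rbf, chi2_model=chi2, hist_model=hist,
                         scaling=scaling, class_ids=class_ids)


def fuse_votes(rbf_pred: np.ndarray, chi2_pred: np.ndarray,
               hist_pred: np.ndarray) -> np.ndarray:
    """Majority vote of three label arrays; three-way splits go to RBF."""
    fused = rbf_pred.copy()
    chi_hist = chi2_pred == hist_pred
    # RBF only loses when the other two agree against it; every other
    # pattern (>=1 agreement with RBF, or full disagreement) returns RBF.
    fused[chi_hist] = chi2_pred[chi_hist]
    return fused


def predict_voxel(model: EnsembleModel, x: np.ndarray) -> int:
    """Fused ensemble label for a single scaled feature vector."""
    x2 = np.atleast_2d(np.asarray(x, dtype=np.float64))
    votes = [int(m.predict(x2)[0]) for m in model.models]
    return int(fuse_votes(*[np.array([v]) for v in votes])[0])


def predict_volume(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Fused ensemble labels for a full (n_voxels, F) scaled feature stack."""
    if X.shape[1] != model.rbf_model.train_rows.shape[1]:
        raise ValueError("feature length does not match the trained model")
    preds = [m.predict(X) for m in model.models]
    return fuse_votes(*preds)
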