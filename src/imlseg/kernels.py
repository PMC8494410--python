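"""The three SVM kernels: RBF, chi-squared, histogram intersection.

All kernels operate on min-max-scaled features in [0, 1]. The chi-squared
and histogram intersection kernels are only defined for nonnegative inputs
and raise on negative entries. Gram matrices for the custom kernels are
computed by numba-compiled loops so that whole-volume prediction (hundreds
of thousands of query rows against the support vectors) stays cheap.

    rbf(x, y)   = exp(-gamma * ||x - y||^2)
    chi2(x, y)  = exp(-gamma * sum_i (x_i - y_i)^2 / (x_i + y_i + eps))
    hist(x, y)  = sum_i min(x_i, y_i)
"""

from __future__ import annotations

import numpy as np
from numba import njit

CHI2_EPS = 1e-10

KERNEL_KINDS = ("rbf", "chi2", "hist_intersection")


def _check_nonnegative(*arrays: np.ndarray) -> None:
    for a in arrays:
        if a.size and a.min() < 0:
            raise ValueError(
                "chi-squared / histogram intersection kernels require "
                "nonnegative features (scale to [0, 1] first)")


def rbf_gram(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """exp(-gamma * squared Euclidean distance), computed via Gram identity."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    sq = (
        (X * X).sum(axis=1)[:, None]
        + (Y * Y).sum(axis=1)[None, :]
        - 2.0 * (X @ Y.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


@njit(cache=True)
def _chi2_dist(X, Y, eps):
    n, m, f = X.shape[0], Y.shape[0], X.shape[1]
    out = np.empty((n, m), dtype=np.float64)
    for i in range(n):
        for j in range(m):
            acc = 0.0
            for k in range(f):
                d = X[i, k] - Y[j, k]
                acc += d * d / (X[i, k] + Y[j, k] + eps)
            out[i, j] = acc
    return out


def chi2_gram(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    _check_nonnegative(X, Y)
    return np.exp(-gamma * _chi2_dist(X, Y, CHI2_EPS))


@njit(cache=True)
def _hist_gram(X, Y):
    n, m, f = X.shape[0], Y.shape[0], X.shape[1]
    out = np.empty((n, m), dtype=np.float64)
    for i in range(n):
        for j in range(m):
            acc = 0.0
            for k in range(f):
                acc += min(X[i, k], Y[j, k])
            out[i, j] = acc
    return out


def hist_intersection_gram(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    X = np.ascontiguousarray(X, dtype=np.float64)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    _check_nonnegative(X, Y)
    return _hist_gram(X, Y)


def kernel_rbf(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Single-pair RBF kernel value."""
    return float(rbf_gram(np.atleast_2d(x), np.atleast_2d(y), gamma)[0, 0])


def kernel_chi2(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Single-pair chi-squared kernel value."""
    return float(chi2_gram(np.atleast_2d(x), np.atleast_2d(y), gamma)[0, 0])


def kernel_hist_intersection(x: np.ndarray, y: np.ndarray) -> float:
    """Single-pair histogram intersection kernel value."""
    return float(hist_intersection_gram(np.atleast_2d(x),
                                        np.atleast_2d(y))[0, 0])


def gram(kind: str, X: np.ndarray, Y: np.ndarray, gamma: float = 1.0
         ) -> np.ndarray:
    """Gram matrix dispatch; ``gamma`` is ignored for hist_intersection."""
    if kind == "rbf":
        return rbf_gram(X, Y, gamma)
    if kind == "chi2":
        return chi2_gram(X, Y, gamma)
    if kind == "hist_intersection":
        return hist_intersection_gram(X, Y)
    raise ValueError(f"unknown kernel kind {kind!r}")
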