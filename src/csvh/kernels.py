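"""Gaussian kernel machinery and the patient-center-shifted kernel.

The classifier works entirely in the reproducing kernel Hilbert space of a
Gaussian kernel

    k(x, y) = exp(-||x - y||^2 / (2 sigma^2)),

so every geometric quantity (center, radius, distance) reduces to kernel
evaluations.  The health-class model additionally uses a *shifted* kernel
k'(x, y) = (phi(x) - a) . (phi(y) - a), the inner product of features
translated so that the patient-class hypersphere center ``a = sum_i beta_i
phi(x_i)`` becomes the origin.  Expanding the translation gives

    k'(x, y) = k(x, y) - sum_i beta_i k(x_i, x) - sum_i beta_i k(x_i, y)
               + sum_ij beta_i beta_j k(x_i, x_j),

which this module evaluates term by term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, InputError

__all__ = [
    "KernelSpec",
    "ShiftedKernelRef",
    "gaussian_kernel",
    "gram_matrix",
    "shifted_kernel",
    "shifted_gram",
    "shifted_diag",
]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel scale.

    Parameters
    ----------
    width : float
        The Gaussian scale sigma.  Must be strictly positive.  Similarities
        satisfy ``0 < k(x, y) <= 1`` with ``k(x, x) = 1``.
    """

    width: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.width) or self.width <= 0:
            raise ConfigError(f"kernel width must be a positive real, got {self.width!r}")


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise InputError(f"expected a vector or a 2-d vector set, got ndim={X.ndim}")
    return X


def gaussian_kernel(x, y, spec: KernelSpec) -> float:
    """Evaluate ``exp(-||x - y||^2 / (2 width^2))`` for a single pair."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InputError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.dot(x - y, x - y))
    return float(np.exp(-d2 / (2.0 * spec.width**2)))


def gram_matrix(X, Y, spec: KernelSpec) -> np.ndarray:
    """Pairwise Gaussian similarities; entry (i, j) = k(X_i, Y_j).

    Empty inputs yield an empty matrix.  With ``X is Y`` the result is
    symmetric positive semidefinite.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        return np.zeros((X.shape[0], Y.shape[0]))
    if X.shape[1] != Y.shape[1]:
        raise InputError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * spec.width**2))


@dataclass
class ShiftedKernelRef:
    """Reference data for the shifted kernel k'.

    Holds the anchor (patient) vectors, their simplex weights beta and the
    precomputed constant ``sum_ij beta_i beta_j k(x_i, x_j)``.
    """

    kernel: KernelSpec
    anchor_points: np.ndarray
    anchor_weights: np.ndarray
    center_norm_sq: float = field(init=False)

    def __post_init__(self) -> None:
        self.anchor_points = _as_2d(self.anchor_points)
        self.anchor_weights = np.asarray(self.anchor_weights, dtype=float).ravel()
        if self.anchor_points.shape[0] == 0:
            raise ConfigError("shifted kernel requires at least one anchor point")
        if self.anchor_points.shape[0] != self.anchor_weights.shape[0]:
            raise ConfigError("anchor_points and anchor_weights length mismatch")
        if np.any(self.anchor_weights < -1e-9):
            raise ConfigError("anchor weights must be nonnegative")
        s = float(self.anchor_weights.sum())
        if abs(s - 1.0) > 1e-9:
            raise ConfigError(f"anchor weights must sum to 1 (got {s})")
        K = gram_matrix(self.anchor_points, self.anchor_points, self.kernel)
        self.center_norm_sq = float(self.anchor_weights @ K @ self.anchor_weights)

    def weighted_similarity(self, X) -> np.ndarray:
        """``sum_i beta_i k(x_i, q)`` for each row q of X."""
        Kx = gram_matrix(self.anchor_points, X, self.kernel)
        return self.anchor_weights @ Kx


def shifted_kernel(x, y, ref: ShiftedKernelRef) -> float:
    """Evaluate k'(x, y) for a single pair (no clamping)."""
    return float(shifted_gram(np.atleast_2d(np.asarray(x, float)),
                              np.atleast_2d(np.asarray(y, float)), ref)[0, 0])


def shifted_gram(X, Y, ref: ShiftedKernelRef) -> np.ndarray:
    """Matrix of k'(X_i, Y_j) values.

    k' is an inner product of translated features, so the Gram matrix of any
    finite set under k' is PSD; off-diagonal values may be negative and the
    diagonal may exceed 1.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    K = gram_matrix(X, Y, ref.kernel)
    sx = ref.weighted_similarity(X)
    sy = ref.weighted_similarity(Y)
    return K - sx[:, None] - sy[None, :] + ref.center_norm_sq


def shifted_diag(X, ref: ShiftedKernelRef) -> np.ndarray:
    """k'(x, x) for each row of X, clamped to ``>= 0``.

    k'(x, x) = ||phi(x) - a||^2, mathematically nonnegative; tiny negative
    values arise from floating-point cancellation near the center and are
    floored at zero before use in square roots or exponents.
    """
    X = _as_2d(X)
    sx = ref.weighted_similarity(X)
    val = 1.0 - 2.0 * sx + ref.center_norm_sq
    return np.maximum(val, 0.0)
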