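"""Rigid-body superposition and the UMD/WMD deviation measurements.

UMD (unweighted mean deviation) is the square of RMSD: the mean of squared
atom-atom distances after the optimal rigid-body superposition.  WMD
(weighted mean deviation) generalizes it with non-negative per-atom
importance weights that sum to one:

    WMD(S, T; beta) = min_{A in SO(3), b} sum_i beta_i * ||A s_i + b - t_i||^2

With uniform weights beta_i = 1/m, WMD equals UMD exactly.  The minimizer is
computed in closed form by weighted Procrustes analysis (Kabsch algorithm
with weight-scaled centroids and covariance, reflection corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "ImportanceWeights",
    "superpose",
    "umd",
    "wmd",
    "weighted_msd",
    "CorrespondenceError",
    "InvalidWeightsError",
]

ORTHOGONALITY_TOL = 1e-8


class CorrespondenceError(ValueError):
    """Site and template atom counts differ."""


class InvalidWeightsError(ValueError):
    """Weight vector violates its constraints."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    unique: bool = True

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthogonal (max error {err:g})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T \
            + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class ImportanceWeights:
    """Per-atom importance weights on the simplex (beta_k)."""

    beta: np.ndarray
    template_id: str = ""

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1:
            raise InvalidWeightsError("beta must be a vector")
        if np.any(self.beta < -1e-12):
            raise InvalidWeightsError("beta entries must be non-negative")
        if abs(self.beta.sum() - 1.0) > 1e-9:
            raise InvalidWeightsError("beta entries must sum to 1")

    @property
    def m(self) -> int:
        return self.beta.size

    @staticmethod
    def uniform(m: int, template_id: str = "") -> "ImportanceWeights":
        return ImportanceWeights(np.full(m, 1.0 / m), template_id)


def _coords_of(obj) -> np.ndarray:
    coords = getattr(obj, "coords", obj)
    if callable(coords):
        coords = coords()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("expected an m x 3 coordinate array")
    return coords


def _check_weights(weights, m: int) -> np.ndarray:
    if weights is None:
        return np.full(m, 1.0 / m)
    if isinstance(weights, ImportanceWeights):
        weights = weights.beta
    w = np.asarray(weights, dtype=float)
    if w.shape != (m,):
        raise InvalidWeightsError(f"expected {m} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise InvalidWeightsError("weights must be non-negative")
    if not np.any(w > 0):
        raise InvalidWeightsError("weights must not be all zero")
    return w


def superpose(site_coords: np.ndarray, template_coords: np.ndarray,
              weights=None) -> RigidTransform:
    """Weighted Procrustes: optimal proper rigid motion of site onto template.

    Minimizes sum_i w_i * ||A s_i + b - t_i||^2 in closed form via SVD of the
    weighted cross-covariance; a reflection in the best orthogonal matrix is
    corrected by flipping the smallest singular direction.  Degenerate
    (rank-deficient) configurations are solved but flagged ``unique=False``.
    """
    S = _coords_of(site_coords)
    T = _coords_of(template_coords)
    if S.shape != T.shape:
        raise CorrespondenceError(
            f"site has {S.shape[0]} atoms, template {T.shape[0]}")
    m = S.shape[0]
    if m < 2:
        raise ValueError("at least 2 atoms required")
    w = _check_weights(weights, m)
    wsum = w.sum()
    s_bar = (w @ S) / wsum
    t_bar = (w @ T) / wsum
    S0 = S - s_bar
    T0 = T - t_bar
    H = (S0 * w[:, None]).T @ T0  # 3x3 weighted covariance
    U, sigma, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    A = Vt.T @ D @ U.T
    # Rotation is unique iff sigma_2 + d*sigma_3 > 0 (non-degenerate rank).
    unique = bool(sigma[1] + d * sigma[2] > ORTHOGONALITY_TOL * max(
        sigma[0], 1.0))
    b = t_bar - A @ s_bar
    return RigidTransform(A, b, unique=unique)


def weighted_msd(site_coords, template_coords, weights=None,
                 transform: RigidTransform | None = None) -> float:
    """Weighted mean of squared distances under a given (or optimal) motion."""
    S = _coords_of(site_coords)
    T = _coords_of(template_coords)
    if S.shape != T.shape:
        raise CorrespondenceError(
            f"site has {S.shape[0]} atoms, template {T.shape[0]}")
    w = _check_weights(weights, S.shape[0])
    w = w / w.sum()
    if transform is None:
        transform = superpose(S, T, w)
    diff = transform.apply(S) - T
    return float(w @ np.einsum("ij,ij->i", diff, diff))


def umd(site, template) -> float:
    """Unweighted mean deviation: RMSD squared (Å²)."""
    S = _coords_of(site)
    return weighted_msd(S, _coords_of(template),
                        np.full(S.shape[0], 1.0 / S.shape[0]))


def wmd(site, template, weights) -> float:
    """Weighted mean deviation (Å²) under importance weights."""
    S = _coords_of(site)
    w = _check_weights(weights, S.shape[0])
    if abs(w.sum() - 1.0) > 1e-6:
        raise InvalidWeightsError("importance weights must sum to 1")
    return weighted_msd(S, _coords_of(template), w)
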