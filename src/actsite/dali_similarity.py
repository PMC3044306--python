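"""Superposition-free similarity via DALI pair scores: MDS and DSDS.

Instead of superposing coordinates, these measurements compare the two
intra-set distance matrices.  For an atom pair with distance d_T in the
template and d_S in the local site, the DALI elastic pair score is

    phi(d_T, d_S) = (0.20 - |d_T - d_S| / d*) * exp(-(d*/20)^2),
    d* = (d_T + d_S) / 2,

with phi = 0.20 when d* = 0 (continuity limit: perfect agreement at zero
distance).  MDS is the mean of phi over all m(m-1)/2 atom pairs; DSDS is a
learned linear combination of the same scores.  Both are invariant to rigid
transforms of either structure by construction.

The similarity threshold (0.20) and envelope width (20 Å) are the published
DALI constants; both are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .geometry import CorrespondenceError, _coords_of

__all__ = [
    "DALI_THRESHOLD",
    "DALI_ENVELOPE",
    "DSDSModel",
    "pair_distances",
    "dali_pair_score",
    "dali_feature_vector",
    "mds",
    "dsds",
    "n_pairs",
]

DALI_THRESHOLD = 0.20
DALI_ENVELOPE = 20.0  # Å


def n_pairs(m: int) -> int:
    return m * (m - 1) // 2


@dataclass
class DSDSModel:
    """Linear coefficients over DALI pair-score features, plus a threshold.

    The threshold is a classification diagnostic; ranking uses the raw
    linear score w · phi(site, template).
    """

    coefficients: np.ndarray
    threshold: float
    template_id: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients,
                                       dtype=float).ravel()
        self.threshold = float(self.threshold)


def pair_distances(coords) -> np.ndarray:
    """All m(m-1)/2 pairwise distances, lexicographic by index pair (i1<i2)."""
    X = _coords_of(coords)
    if X.shape[0] < 2:
        raise ValueError("at least 2 atoms required for pair distances")
    return pdist(X)


def dali_pair_score(d_T, d_S, threshold: float = DALI_THRESHOLD,
                    envelope: float = DALI_ENVELOPE):
    """DALI elastic score of one corresponding distance pair (vectorized)."""
    d_T = np.asarray(d_T, dtype=float)
    d_S = np.asarray(d_S, dtype=float)
    if np.any(d_T < 0) or np.any(d_S < 0):
        raise ValueError("distances must be non-negative")
    d_star = 0.5 * (d_T + d_S)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(d_star > 0, np.abs(d_T - d_S) / np.where(
            d_star > 0, d_star, 1.0), 0.0)
    score = (threshold - rel) * np.exp(-((d_star / envelope) ** 2))
    if score.ndim == 0:
        return float(score)
    return score


def dali_feature_vector(site, template, threshold: float = DALI_THRESHOLD,
                        envelope: float = DALI_ENVELOPE) -> np.ndarray:
    """Vector of DALI pair scores for every corresponding atom pair."""
    S = _coords_of(site)
    T = _coords_of(template)
    if S.shape != T.shape:
        raise CorrespondenceError(
            f"site has {S.shape[0]} atoms, template {T.shape[0]}")
    return np.asarray(dali_pair_score(pair_distances(T), pair_distances(S),
                                      threshold, envelope))


def mds(site, template, threshold: float = DALI_THRESHOLD,
        envelope: float = DALI_ENVELOPE) -> float:
    """Mean DALI score over all atom pairs (unlearned control similarity)."""
    return float(np.mean(dali_feature_vector(site, template, threshold,
                                             envelope)))


def dsds(site, template, model: DSDSModel,
         threshold: float = DALI_THRESHOLD,
         envelope: float = DALI_ENVELOPE) -> float:
    """Learned linear combination of DALI pair scores (higher = more similar).

    No bias term is added; the model threshold is used only as a
    classification diagnostic.
    """
    features = dali_feature_vector(site, template, threshold, envelope)
    if model.coefficients.size != features.size:
        raise ValueError(
            f"model has {model.coefficients.size} coefficients; template "
            f"needs {features.size}")
    return float(model.coefficients @ features)
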