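"""Post-processing: cross-template comparable confidences.

Per-template similarities or deviations cannot be compared across templates
directly, so the multiple-template analysis converts them into unified
scores:

* **LR** — logistic regression posterior P(active | measurement), fitted
  per template on training labels.
* **PINTS** — a significance scheme for deviation measurements only: the
  weighted RMSD (√WMD or √UMD) of a candidate is converted to the log of the
  expected number of random local sites matching at least that well.  The
  null is fitted per template as a Gumbel (minimum) location-scale model on
  negative-site deviations; a size-dependent penalty makes matches of larger
  templates rarer.  More negative log-frequency = more significant.
* **Direct** — the raw measurement, usable across templates only within one
  measurement family (the experimental control).

PINTS applies to deviations only; requesting it for the similarity
measurements (MDS/DSDS) is a configuration error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gumbel_l
from sklearn.linear_model import LogisticRegression

from .learn_wmd import TrainingSetError
from .structures_io import Template

__all__ = [
    "LRModel",
    "PintsModel",
    "fit_lr",
    "lr_posterior",
    "fit_pints_null",
    "pints_logF",
    "merge_rankings",
    "ScoredSite",
    "ConfigurationError",
    "default_size_penalty",
]


class ConfigurationError(ValueError):
    """Incompatible measurement/post-processing combination."""


@dataclass
class LRModel:
    slope: float
    intercept: float
    template_id: str = ""
    orientation: str = "similarity"  # or "deviation"


@dataclass
class PintsModel:
    """Gumbel(min) null model of negative-site deviations (Å)."""

    template_id: str
    null_location: float
    null_scale: float
    matched_atom_count: int
    n_negatives: int

    def __post_init__(self) -> None:
        if self.null_scale <= 0:
            raise ValueError("null_scale must be positive")

    def null_cdf(self, deviation: float) -> float:
        return float(gumbel_l.cdf(deviation, loc=self.null_location,
                                  scale=self.null_scale))

    def expected_frequency(self, deviation: float) -> float:
        """Expected number of negatives deviating at most this much."""
        return self.n_negatives * self.null_cdf(deviation)


def fit_lr(scores: Sequence[float], labels: Sequence[int],
           template_id: str = "", orientation: str = "similarity"
           ) -> LRModel:
    """Maximum-likelihood logistic fit of P(+1 | score).

    A tiny ridge (1e-6) keeps the coefficients bounded under complete
    separation, which is reported with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (np.any(y == 1) and np.any(y == -1)):
        raise TrainingSetError("both classes required for logistic fit")
    pos, neg = scores[y == 1], scores[y == -1]
    separated = pos.min() > neg.max() or pos.max() < neg.min()
    if separated:
        warnings.warn("classes completely separated; logistic coefficients "
                      "bounded by the 1e-6 ridge", stacklevel=2)
    clf = LogisticRegression(C=1e6, tol=1e-12, max_iter=100_000)
    clf.fit(scores.reshape(-1, 1), y)
    # sklearn orients coefficients toward the label +1 class
    return LRModel(slope=float(clf.coef_[0, 0]),
                   intercept=float(clf.intercept_[0]),
                   template_id=template_id, orientation=orientation)


def lr_posterior(model: LRModel, score: float) -> float:
    """Posterior probability of the positive class at a measurement value."""
    z = model.slope * float(score) + model.intercept
    return float(expit(z))


def default_size_penalty(matched_atom_count: int) -> float:
    """Log abundance penalty: each matched atom halves the expected random
    match frequency (heuristic hook; replaceable)."""
    return matched_atom_count * math.log(2.0)


def fit_pints_null(negative_deviations: Sequence[float], template: Template
                   ) -> PintsModel:
    """Fit the per-template null from negative-site deviations (√WMD, Å)."""
    devs = np.asarray(negative_deviations, dtype=float)
    if devs.size < 20:
        raise ValueError(
            f"need at least 20 negative deviations, got {devs.size}")
    loc, scale = gumbel_l.fit(devs)
    return PintsModel(template_id=template.template_id,
                      null_location=float(loc), null_scale=float(scale),
                      matched_atom_count=template.m, n_negatives=devs.size)


def pints_logF(model: PintsModel, deviation: float,
               size_penalty: Callable[[int], float] = default_size_penalty
               ) -> float:
    """Log expected frequency of a match at least this good, size-penalized.

    Strictly increasing in the deviation; decreasing in the matched atom
    count at fixed deviation.  More negative = more significant.
    """
    z = (float(deviation) - model.null_location) / model.null_scale
    # Gumbel(min) log CDF = log(1 - exp(-exp(z))), computed stably: the
    # log1p form stays strictly monotone far into the upper tail.
    if z < 0 or np.exp(z) < 700:
        logcdf = float(np.log1p(-np.exp(-np.exp(z))))
    else:  # CDF indistinguishable from 1 in double precision
        logcdf = 0.0
    return math.log(model.n_negatives) + logcdf \
        - size_penalty(model.matched_atom_count)


# ---------------------------------------------------------------------------
# Ranking merge
# ---------------------------------------------------------------------------

@dataclass
class ScoredSite:
    """One (site, template) row of a prediction table."""

    structure_id: str
    residue_label: str
    template_id: str
    score: float  # raw measurement value
    orientation: str  # "similarity" or "deviation"
    confidence: float | None = None  # post-processed value, if any


def merge_rankings(rows: list[ScoredSite], method: str) -> pd.DataFrame:
    """Merge per-template scored sites into one ranked table.

    ``method`` is one of direct / lr / pints.  LR sorts descending by
    posterior; PINTS ascending by log-frequency; Direct by the raw score
    (descending for similarities, ascending for deviations) and refuses to
    mix orientations across templates.  Duplicate (site, template) rows from
    different templates are retained.  Ties break by (structure_id, residue
    label) so the order is deterministic.
    """
    if method not in ("direct", "lr", "pints"):
        raise ConfigurationError(f"unknown post-processing {method!r}")
    if not rows:
        return pd.DataFrame(columns=["rank", "structure_id", "residues",
                                     "template_id", "score", "confidence",
                                     "method"])
    orientations = {r.orientation for r in rows}
    if method == "direct":
        if len(orientations) > 1:
            raise ConfigurationError(
                "direct merging across different measurement families "
                "is not comparable")
        orientation = orientations.pop()
        keyed = [(-r.score if orientation == "similarity" else r.score,
                  r.structure_id, r.residue_label, r) for r in rows]
        confidence = [r.score for r in rows]
    elif method == "lr":
        keyed = [(-(r.confidence if r.confidence is not None else 0.0),
                  r.structure_id, r.residue_label, r) for r in rows]
        confidence = None
    else:  # pints
        if any(r.orientation != "deviation" for r in rows):
            raise ConfigurationError(
                "PINTS applies only to deviation measurements")
        keyed = [(r.confidence if r.confidence is not None else 0.0,
                  r.structure_id, r.residue_label, r) for r in rows]
        confidence = None
    keyed.sort(key=lambda t: t[:3])
    ordered = [t[3] for t in keyed]
    return pd.DataFrame({
        "rank": np.arange(1, len(ordered) + 1),
        "structure_id": [r.structure_id for r in ordered],
        "residues": [r.residue_label for r in ordered],
        "template_id": [r.template_id for r in ordered],
        "score": [r.score for r in ordered],
        "confidence": [r.confidence if r.confidence is not None else r.score
                       for r in ordered],
        "method": method,
    })
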