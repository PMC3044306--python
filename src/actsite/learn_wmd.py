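"""Learning per-atom importance weights for the WMD deviation.

The training objective asks for importance weights beta (on the simplex,
capped at 2/m to avoid over-fitting) and a threshold theta such that
positive sites deviate less than theta - eps and negative sites more than
theta + eps, penalizing violations with per-site costs C_j (1/n_plus for
positives, 1/n_minus for negatives):

    minimize sum_j C_j * loss_j(beta, theta)

Because the deviation itself contains a minimization over rigid transforms,
this is a bi-level program.  It is solved by a two-stage alternation:

1. LP stage — with the per-site transforms frozen, each deviation is linear
   in beta, so the hinge-loss minimization over (beta, theta) is a linear
   program, solved exactly.
2. Transform stage — with beta frozen, each site's optimal transform is a
   weighted Procrustes problem, solved in closed form.

Transforms are initialized by unweighted superposition (the UMD optimum) and
the two stages alternate for a fixed number of iterations (2 by default).
The scheme is a local heuristic; no global-optimality guarantee holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .geometry import (ImportanceWeights, RigidTransform, superpose)
from .lss import LocalSite
from .structures_io import Template

__all__ = [
    "WMDModel",
    "WMDTrainingSet",
    "site_distance_features",
    "lp_stage",
    "transform_stage",
    "train_wmd",
    "TrainingSetError",
]

DEFAULT_EPSILON = 0.01  # Å²; margin half-width of the hinge loss


class TrainingSetError(ValueError):
    """Training set lacks a class or is otherwise unusable."""


@dataclass
class WMDModel:
    weights: ImportanceWeights
    threshold: float
    epsilon: float
    iterations_used: int
    objective_history: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kind": "wmd",
            "template_id": self.weights.template_id,
            "beta": self.weights.beta.tolist(),
            "threshold": self.threshold,
            "epsilon": self.epsilon,
            "iterations_used": self.iterations_used,
            "objective_history": self.objective_history,
        }, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "WMDModel":
        data = json.loads(Path(path).read_text())
        if data.get("kind") != "wmd":
            raise ValueError(f"{path}: not a WMD model file")
        return WMDModel(
            weights=ImportanceWeights(np.array(data["beta"]),
                                      data["template_id"]),
            threshold=float(data["threshold"]),
            epsilon=float(data["epsilon"]),
            iterations_used=int(data["iterations_used"]),
            objective_history=list(data.get("objective_history", [])))


@dataclass
class WMDTrainingSet:
    """Labeled local sites of one template with class-balanced costs."""

    sites: list[LocalSite]
    costs: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = np.array([s.label for s in self.sites])
        n_pos = int((labels == 1).sum())
        n_neg = int((labels == -1).sum())
        if n_pos == 0 or n_neg == 0:
            raise TrainingSetError(
                f"need both classes; got {n_pos} positives, {n_neg} negatives")
        if self.costs is None:
            self.costs = np.where(labels == 1, 1.0 / n_pos, 1.0 / n_neg)
        self.costs = np.asarray(self.costs, dtype=float)
        self.labels = labels
        self.n_pos = n_pos
        self.n_neg = n_neg


def site_distance_features(site, template, transform: RigidTransform
                           ) -> np.ndarray:
    """Per-atom squared distances under a fixed transform.

    The deviation is the dot product of beta with this vector, so the vector
    is exactly the LP-stage feature row for one site.
    """
    S = np.asarray(getattr(site, "coords", site), dtype=float)
    T = np.asarray(getattr(template, "coords", template), dtype=float)
    if S.shape != T.shape:
        from .geometry import CorrespondenceError
        raise CorrespondenceError(
            f"site has {S.shape[0]} atoms, template {T.shape[0]}")
    diff = transform.apply(S) - T
    return np.einsum("ij,ij->i", diff, diff)


def lp_stage(feature_matrix: np.ndarray, labels: np.ndarray,
             costs: np.ndarray, epsilon: float, m_k: int | None = None,
             template_id: str = ""
             ) -> tuple[ImportanceWeights, float, float]:
    """Exact hinge-loss minimization over (beta, theta) as a linear program.

    Variables are beta (m, on the simplex with cap 2/m), theta (free) and
    per-site slacks xi >= 0; minimizes sum_j costs_j * xi_j subject to

        y_j = +1:  xi_j >= beta·f_j - (theta - epsilon)
        y_j = -1:  xi_j >= (theta + epsilon) - beta·f_j

    Returns (weights, theta, objective value).
    """
    F = np.asarray(feature_matrix, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("feature matrix must be finite")
    y = np.asarray(labels)
    n, m = F.shape
    if m_k is None:
        m_k = m
    if not (np.any(y == 1) and np.any(y == -1)):
        raise TrainingSetError("both classes required in the LP stage")
    # Variable layout: [beta_0..beta_{m-1}, theta, xi_0..xi_{n-1}]
    c = np.concatenate([np.zeros(m), [0.0], np.asarray(costs, dtype=float)])
    A_ub = np.zeros((n, m + 1 + n))
    b_ub = np.zeros(n)
    for j in range(n):
        if y[j] == 1:
            A_ub[j, :m] = F[j]
            A_ub[j, m] = -1.0
        else:
            A_ub[j, :m] = -F[j]
            A_ub[j, m] = 1.0
        A_ub[j, m + 1 + j] = -1.0
        b_ub[j] = -epsilon
    A_eq = np.zeros((1, m + 1 + n))
    A_eq[0, :m] = 1.0
    b_eq = np.array([1.0])
    bounds = [(0.0, 2.0 / m_k)] * m + [(None, None)] + [(0.0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    beta = np.clip(res.x[:m], 0.0, 2.0 / m_k)
    beta = beta / beta.sum()
    theta = float(res.x[m])
    return ImportanceWeights(beta, template_id), theta, float(res.fun)


def transform_stage(sites, template, weights: ImportanceWeights
                    ) -> list[RigidTransform]:
    """Per-site weighted Procrustes optimum under the current weights."""
    T = np.asarray(getattr(template, "coords", template), dtype=float)
    return [superpose(np.asarray(getattr(s, "coords", s), dtype=float), T,
                      weights) for s in sites]


def hinge_objective(feature_matrix, labels, costs, beta, theta,
                    epsilon) -> float:
    """Cost-weighted hinge loss at a given (beta, theta) — diagnostics."""
    delta = np.asarray(feature_matrix) @ np.asarray(beta)
    y = np.asarray(labels)
    loss = np.where(y == 1,
                    np.maximum(0.0, delta - (theta - epsilon)),
                    np.maximum(0.0, (theta + epsilon) - delta))
    return float(np.asarray(costs) @ loss)


def train_wmd(training: WMDTrainingSet, template: Template,
              iterations: int = 2, epsilon: float = DEFAULT_EPSILON
              ) -> WMDModel:
    """Alternate LP and transform stages to fit (beta, theta).

    Transforms start at the unweighted (UMD) optima.  The surrogate hinge
    objective after each LP stage is recorded; the overall loss is not
    guaranteed to decrease monotonically across full iterations.
    """
    if iterations < 1:
        raise ValueError("at least one iteration required")
    T = template.coords
    m = template.m
    transforms = transform_stage(training.sites, template,
                                 ImportanceWeights.uniform(m))
    weights = ImportanceWeights.uniform(m, template.template_id)
    theta = 0.0
    history: list[float] = []
    for _ in range(iterations):
        F = np.array([site_distance_features(s, T, tr)
                      for s, tr in zip(training.sites, transforms)])
        weights, theta, objective = lp_stage(
            F, training.labels, training.costs, epsilon, m_k=m,
            template_id=template.template_id)
        history.append(objective)
        transforms = transform_stage(training.sites, template, weights)
    return WMDModel(weights=weights, threshold=theta, epsilon=epsilon,
                    iterations_used=iterations, objective_history=history)
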