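"""Learning DSDS coefficients with a cost-weighted soft-margin SVC.

The training objective over coefficients w and threshold theta is

    minimize  (1/2)||w||^2 + sum_j C_j * loss_j(w, theta)

with hinge losses max(0, (theta + eps) - w·x_j) for positives and
max(0, w·x_j - (theta - eps)) for negatives, i.e. the standard soft-margin
linear SVC with per-sample costs and bias -theta.  Costs default to
1000/n_plus for positive sites and 1000/n_minus for negative sites.

With eps = 1 this is exactly the canonical unit-margin SVC.  For other
eps > 0 the problem is solved by rescaling: substituting w = eps*w',
theta = eps*theta' reduces it to a unit-margin SVC with sample weights
C_j/eps, whose solution is scaled back by eps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .dali_similarity import DSDSModel, dsds
from .learn_wmd import TrainingSetError

__all__ = ["DSDSTrainingSet", "train_dsds", "predict_dsds",
           "svc_objective", "DEFAULT_COST_SCALE"]

DEFAULT_COST_SCALE = 1000.0


@dataclass
class DSDSTrainingSet:
    """DALI pair-score features with labels and class-balanced costs."""

    feature_matrix: np.ndarray
    labels: np.ndarray
    costs: np.ndarray = None  # type: ignore[assignment]
    cost_scale: float = DEFAULT_COST_SCALE

    def __post_init__(self) -> None:
        self.feature_matrix = np.asarray(self.feature_matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isfinite(self.feature_matrix)):
            raise ValueError("feature matrix must be finite")
        n_pos = int((self.labels == 1).sum())
        n_neg = int((self.labels == -1).sum())
        if n_pos == 0 or n_neg == 0:
            raise TrainingSetError(
                f"need both classes; got {n_pos} positives, {n_neg} negatives")
        if self.costs is None:
            self.costs = np.where(self.labels == 1,
                                  self.cost_scale / n_pos,
                                  self.cost_scale / n_neg)
        self.costs = np.asarray(self.costs, dtype=float)


def svc_objective(features, labels, costs, w, theta,
                  epsilon: float = 1.0) -> float:
    """Value of the regularized hinge objective at (w, theta) — diagnostics."""
    w = np.asarray(w, dtype=float).ravel()
    margins = np.asarray(features) @ w
    y = np.asarray(labels)
    loss = np.where(y == 1,
                    np.maximum(0.0, (theta + epsilon) - margins),
                    np.maximum(0.0, margins - (theta - epsilon)))
    return float(0.5 * w @ w + np.asarray(costs) @ loss)


def train_dsds(training: DSDSTrainingSet, epsilon: float = 1.0,
               template_id: str = "") -> DSDSModel:
    """Fit (w, theta) by the cost-weighted soft-margin linear SVC."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    clf = SVC(kernel="linear", C=1.0, tol=1e-8)
    clf.fit(training.feature_matrix, training.labels,
            sample_weight=training.costs / epsilon)
    w = epsilon * clf.coef_.ravel()
    theta = -epsilon * float(clf.intercept_[0])
    return DSDSModel(coefficients=w, threshold=theta,
                     template_id=template_id)


def predict_dsds(model: DSDSModel, site, template) -> float:
    """Similarity of a site to the template (higher = more template-like)."""
    return dsds(site, template, model)


def dsds_model_to_json(model: DSDSModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "kind": "dsds",
        "template_id": model.template_id,
        "coefficients": model.coefficients.tolist(),
        "threshold": model.threshold,
    }, indent=1))


def dsds_model_from_json(path: str | Path) -> DSDSModel:
    data = json.loads(Path(path).read_text())
    if data.get("kind") != "dsds":
        raise ValueError(f"{path}: not a DSDS model file")
    return DSDSModel(coefficients=np.array(data["coefficients"]),
                     threshold=float(data["threshold"]),
                     template_id=data["template_id"])
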