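"""ROC evaluation and the repeated-split protocol.

Metrics: ROC score (area under the ROC curve, equal to the Mann-Whitney
pair statistic), ROC5 score (area up to the fifth false positive, normalized
to [0, 1]), and Sensitivity at 95% specificity (the conservative
step-function convention: the TPR at the largest achievable FPR not
exceeding 5%).

The experiment protocol splits the structure set 50/50 into training and
test halves, repairs each split so every template keeps at least one
positive-bearing structure in the training half, and repeats (30 times by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "EvalReport",
    "SplitPlan",
    "roc_score",
    "roc5_score",
    "sensitivity_at_specificity",
    "roc_curve_points",
    "make_splits",
    "aggregate_curves",
    "UndefinedMetricError",
    "SplitError",
]


class UndefinedMetricError(ValueError):
    """Metric needs both classes present."""


class SplitError(ValueError):
    """Split constraint cannot be satisfied."""


@dataclass
class EvalReport:
    roc: float
    roc5: float
    sensitivity_at_95spec: float
    curve: np.ndarray  # (k, 2) array of (FPR, TPR) points
    grouping: str = "per_template"


@dataclass
class SplitPlan:
    seed: int
    repeat: int
    train_ids: frozenset
    test_ids: frozenset


def _check_classes(labels: np.ndarray) -> None:
    if not (np.any(labels == 1) and np.any(labels == -1)):
        raise UndefinedMetricError("both classes required")


def roc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; ties count half (Mann-Whitney statistic)."""
    y = np.asarray(labels, dtype=int)
    _check_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_curve_points(scores, labels) -> np.ndarray:
    """Full (FPR, TPR) step curve from (0,0) to (1,1); tied scores form a
    single threshold step (diagonal segment)."""
    y = np.asarray(labels, dtype=int)
    _check_classes(y)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float),
                            drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def roc5_score(scores, labels, n_fp: int = 5) -> float:
    """Area under the ROC curve up to the first ``n_fp`` false positives,
    normalized so a perfect ranking scores 1.0.

    If fewer than ``n_fp`` negatives exist, all of them are used (the score
    then coincides with the plain ROC score).
    """
    y = np.asarray(labels, dtype=int)
    _check_classes(y)
    n_neg = int((y == -1).sum())
    fp_max = min(n_fp, n_neg)
    curve = roc_curve_points(scores, y)
    fp = curve[:, 0] * n_neg  # false-positive counts
    tpr = curve[:, 1]
    area = 0.0
    for (f0, t0), (f1, t1) in zip(zip(fp, tpr), zip(fp[1:], tpr[1:])):
        if f0 >= fp_max:
            break
        if f1 <= fp_max:
            area += 0.5 * (t0 + t1) * (f1 - f0)
        else:  # clip the segment at fp_max by linear interpolation
            t_clip = t0 + (t1 - t0) * (fp_max - f0) / (f1 - f0)
            area += 0.5 * (t0 + t_clip) * (fp_max - f0)
            break
    return float(area / fp_max)


def sensitivity_at_specificity(scores, labels,
                               specificity: float = 0.95) -> float:
    """TPR at the largest achievable FPR not exceeding 1 - specificity."""
    curve = roc_curve_points(scores, labels)
    fpr_cap = 1.0 - specificity + 1e-12
    admissible = curve[curve[:, 0] <= fpr_cap]
    return float(admissible[:, 1].max()) if admissible.size else 0.0


# ---------------------------------------------------------------------------
# Repeated-split protocol
# ---------------------------------------------------------------------------

def make_splits(positives_by_structure: Mapping[str, set],
                n_repeats: int = 30, seed: int = 0,
                max_repairs: int = 10_000) -> list[SplitPlan]:
    """Random 50/50 structure-level splits with per-template coverage.

    ``positives_by_structure`` maps structure_id to the set of template ids
    for which the structure carries at least one positive site (possibly
    empty).  Each split is repaired by swapping structures between halves
    until every template has at least one positive-bearing structure in the
    training half.  Deterministic given the seed.
    """
    structure_ids = sorted(positives_by_structure)
    carriers: dict[str, list[str]] = {}
    for sid, tids in positives_by_structure.items():
        for tid in tids:
            carriers.setdefault(tid, []).append(sid)
    for tid, sids in carriers.items():
        if len(sids) < 2:
            raise SplitError(
                f"template {tid!r} has positives in {len(sids)} structure(s);"
                " at least 2 required for a 50/50 split")
    rng = np.random.default_rng(seed)
    plans: list[SplitPlan] = []
    for repeat in range(n_repeats):
        perm = list(rng.permutation(structure_ids))
        half = len(perm) // 2
        train = set(perm[:half])
        test = set(perm[half:])
        repairs = 0
        while True:
            uncovered = [tid for tid, sids in carriers.items()
                         if not any(s in train for s in sids)]
            if not uncovered:
                break
            repairs += 1
            if repairs > max_repairs:
                raise SplitError(
                    f"could not satisfy coverage for template "
                    f"{uncovered[0]!r} after {max_repairs} repairs")
            tid = uncovered[0]
            incoming = carriers[tid][int(rng.integers(len(carriers[tid])))]
            # Swap against a training structure that is not the sole
            # training carrier of some other template.
            sole = set()
            for other, sids in carriers.items():
                train_carriers = [s for s in sids if s in train]
                if len(train_carriers) == 1:
                    sole.add(train_carriers[0])
            movable = sorted(train - sole)
            if not movable:
                raise SplitError(
                    f"no movable structure to cover template {tid!r}")
            outgoing = movable[int(rng.integers(len(movable)))]
            train.remove(outgoing)
            test.add(outgoing)
            test.remove(incoming)
            train.add(incoming)
        plans.append(SplitPlan(seed=seed, repeat=repeat,
                               train_ids=frozenset(train),
                               test_ids=frozenset(test)))
    return plans


def aggregate_curves(curves: Sequence[np.ndarray],
                     percentiles: Sequence[float] = (25, 50, 75),
                     grid: np.ndarray | None = None
                     ) -> dict[float, np.ndarray]:
    """Percentile TPR curves across a set of ROC curves.

    Each curve is resampled onto a common FPR grid by linear interpolation;
    at every grid point the requested TPR percentiles are taken across
    curves.  Returns {percentile: (len(grid), 2) array of (FPR, TPR)}.
    """
    if len(curves) == 0:
        raise ValueError("at least one curve required")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    tprs = np.array([np.interp(grid, c[:, 0], c[:, 1]) for c in curves])
    return {float(p): np.column_stack([grid, np.percentile(tprs, p, axis=0)])
            for p in percentiles}
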