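"""End-to-end analyses: single-template, multiple-template, experiment.

* Single template analysis: one template queried against many structures —
  local site search, then similarity/deviation per candidate, sorted
  descending (similarities) or ascending (deviations).
* Multiple template analysis: one protein queried against a template
  library — search per template, scoring, then post-processing into
  cross-template comparable confidences and a merged ranking.
* Experiment: the repeated-split protocol — 50/50 structure splits with
  per-template positive coverage, per-template models trained on the
  training half only, all measurement × post-processing combinations
  evaluated on the held-out half, means reported over repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dali_similarity, evaluation, geometry, lss
from .dali_similarity import DSDSModel, dali_feature_vector
from .learn_dsds import DSDSTrainingSet, train_dsds
from .learn_wmd import WMDModel, WMDTrainingSet, train_wmd
from .lss import LocalSite
from .postprocess import (ConfigurationError, LRModel, PintsModel,
                          ScoredSite, fit_lr, fit_pints_null, lr_posterior,
                          merge_rankings, pints_logF)
from .structures_io import ProteinStructure, Template

logger = logging.getLogger("actsite")

__all__ = [
    "RunConfig",
    "RankedPrediction",
    "MEASUREMENTS",
    "POSTPROCESSINGS",
    "measurement_orientation",
    "score_site",
    "run_single_template",
    "run_multiple_template",
    "run_experiment",
]

MEASUREMENTS = ("umd", "wmd", "mds", "dsds")
POSTPROCESSINGS = ("direct", "lr", "pints")

DEVIATION_MEASUREMENTS = frozenset({"umd", "wmd"})


def measurement_orientation(measurement: str) -> str:
    return "deviation" if measurement in DEVIATION_MEASUREMENTS \
        else "similarity"


@dataclass
class RunConfig:
    measurement: str = "umd"
    postprocessing: str = "direct"
    rmsd_cutoff: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement not in MEASUREMENTS:
            raise ConfigurationError(
                f"unknown measurement {self.measurement!r}")
        if self.postprocessing not in POSTPROCESSINGS:
            raise ConfigurationError(
                f"unknown post-processing {self.postprocessing!r}")
        if self.postprocessing == "pints" and \
                self.measurement not in DEVIATION_MEASUREMENTS:
            raise ConfigurationError(
                "PINTS applies only to the deviation measurements "
                "(UMD/WMD), not to MDS/DSDS")


@dataclass
class RankedPrediction:
    """Ranked (site, template) rows; the output table of both analyses."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        ranks = self.rows["rank"].to_numpy()
        if len(ranks) and not np.array_equal(ranks,
                                             np.arange(1, len(ranks) + 1)):
            raise ValueError("ranks must be 1..n in order")

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def score_site(site: LocalSite, template: Template, measurement: str,
               wmd_model: WMDModel | None = None,
               dsds_model: DSDSModel | None = None) -> float:
    if measurement == "umd":
        return geometry.umd(site.coords, template.coords)
    if measurement == "wmd":
        if wmd_model is None:
            raise ConfigurationError("wmd measurement requires a WMD model")
        return geometry.wmd(site.coords, template.coords, wmd_model.weights)
    if measurement == "mds":
        return dali_similarity.mds(site.coords, template.coords)
    if measurement == "dsds":
        if dsds_model is None:
            raise ConfigurationError("dsds measurement requires a DSDS model")
        return dali_similarity.dsds(site.coords, template.coords, dsds_model)
    raise ConfigurationError(f"unknown measurement {measurement!r}")


def run_single_template(template: Template,
                        structures: Sequence[ProteinStructure],
                        config: RunConfig,
                        wmd_model: WMDModel | None = None,
                        dsds_model: DSDSModel | None = None
                        ) -> RankedPrediction:
    """Search all structures with one template and rank the candidates."""
    orientation = measurement_orientation(config.measurement)
    rows: list[ScoredSite] = []
    for structure in structures:
        for site in lss.search(structure, template, config.rmsd_cutoff):
            value = score_site(site, template, config.measurement,
                               wmd_model, dsds_model)
            rows.append(ScoredSite(
                structure_id=site.structure_id,
                residue_label=site.residue_label(),
                template_id=template.template_id,
                score=value, orientation=orientation))
    logger.info("single-template %s: %d candidate sites",
                template.template_id, len(rows))
    return RankedPrediction(merge_rankings(rows, "direct"))


def _confidence(row: ScoredSite, postprocessing: str,
                lr_models: Mapping[str, LRModel] | None,
                pints_models: Mapping[str, PintsModel] | None) -> float:
    if postprocessing == "direct":
        return row.score
    if postprocessing == "lr":
        if lr_models is None or row.template_id not in lr_models:
            raise ConfigurationError(
                f"no LR model for template {row.template_id!r}")
        return lr_posterior(lr_models[row.template_id], row.score)
    if postprocessing == "pints":
        if row.orientation != "deviation":
            raise ConfigurationError(
                "PINTS applies only to deviation measurements")
        if pints_models is None or row.template_id not in pints_models:
            raise ConfigurationError(
                f"no PINTS model for template {row.template_id!r}")
        return pints_logF(pints_models[row.template_id],
                          float(np.sqrt(row.score)))
    raise ConfigurationError(f"unknown post-processing {postprocessing!r}")


def run_multiple_template(protein: ProteinStructure,
                          templates: Sequence[Template],
                          config: RunConfig,
                          wmd_models: Mapping[str, WMDModel] | None = None,
                          dsds_models: Mapping[str, DSDSModel] | None = None,
                          lr_models: Mapping[str, LRModel] | None = None,
                          pints_models: Mapping[str, PintsModel] | None = None
                          ) -> RankedPrediction:
    """Scan one protein with a template library and merge the rankings.

    A site hit by several templates yields one output row per template.
    """
    rows: list[ScoredSite] = []
    orientation = measurement_orientation(config.measurement)
    for template in templates:
        tid = template.template_id
        wmd_model = (wmd_models or {}).get(tid)
        dsds_model = (dsds_models or {}).get(tid)
        for site in lss.search(protein, template, config.rmsd_cutoff):
            value = score_site(site, template, config.measurement,
                               wmd_model, dsds_model)
            row = ScoredSite(structure_id=site.structure_id,
                             residue_label=site.residue_label(),
                             template_id=tid, score=value,
                             orientation=orientation)
            row.confidence = _confidence(row, config.postprocessing,
                                         lr_models, pints_models)
            rows.append(row)
    logger.info("multiple-template %s: %d (site, template) rows",
                protein.structure_id, len(rows))
    return RankedPrediction(merge_rankings(rows, config.postprocessing))


# ---------------------------------------------------------------------------
# Repeated-split experiment
# ---------------------------------------------------------------------------

def _train_models(train_sites: Mapping[str, list[LocalSite]],
                  templates: Mapping[str, Template],
                  wmd_iterations: int, wmd_epsilon: float
                  ) -> tuple[dict, dict]:
    wmd_models: dict[str, WMDModel] = {}
    dsds_models: dict[str, DSDSModel] = {}
    for tid, sites in train_sites.items():
        template = templates[tid]
        training = WMDTrainingSet(sites=sites)
        wmd_models[tid] = train_wmd(training, template,
                                    iterations=wmd_iterations,
                                    epsilon=wmd_epsilon)
        features = np.array([dali_feature_vector(s.coords, template.coords)
                             for s in sites])
        labels = np.array([s.label for s in sites])
        dsds_models[tid] = train_dsds(
            DSDSTrainingSet(feature_matrix=features, labels=labels),
            template_id=tid)
    return wmd_models, dsds_models


def run_experiment(sites_by_template: Mapping[str, list[LocalSite]],
                   templates: Mapping[str, Template],
                   n_repeats: int = 30, seed: int = 0,
                   measurements: Sequence[str] = MEASUREMENTS,
                   postprocessings: Sequence[str] = ("direct",),
                   wmd_iterations: int = 2, wmd_epsilon: float = 0.01,
                   ) -> tuple[pd.DataFrame, dict]:
    """Train/evaluate all requested combinations over repeated 50/50 splits.

    Sites are split at the structure level; models (WMD, DSDS, LR, PINTS)
    are fitted on training-half sites only.  Single-template metrics pool
    test sites per template; multiple-template (per-protein) metrics are
    computed over (site, template) rows of each test structure that carries
    both classes.  Returns the summary table and an audit record proving
    test structures never entered a fit.
    """
    positives_by_structure: dict[str, set] = {}
    for tid, sites in sites_by_template.items():
        for s in sites:
            positives_by_structure.setdefault(s.structure_id, set())
            if s.label == 1:
                positives_by_structure[s.structure_id].add(tid)
    plans = evaluation.make_splits(positives_by_structure,
                                   n_repeats=n_repeats, seed=seed)
    records = []
    audit = {"repeats": []}
    for plan in plans:
        train_sites = {tid: [s for s in sites
                             if s.structure_id in plan.train_ids]
                       for tid, sites in sites_by_template.items()}
        test_sites = {tid: [s for s in sites
                            if s.structure_id in plan.test_ids]
                      for tid, sites in sites_by_template.items()}
        touched = sorted({s.structure_id
                          for sites in train_sites.values() for s in sites})
        audit["repeats"].append({
            "repeat": plan.repeat,
            "trained_on": touched,
            "disjoint_from_test": not (set(touched) & set(plan.test_ids)),
        })
        wmd_models, dsds_models = _train_models(
            train_sites, templates, wmd_iterations, wmd_epsilon)

        # Raw measurement values on both halves.
        def score_all(sites_map, half):
            values: dict[tuple[str, str], np.ndarray] = {}
            for tid, sites in sites_map.items():
                template = templates[tid]
                for meas in measurements:
                    values[(tid, meas)] = np.array([
                        score_site(s, template, meas,
                                   wmd_models.get(tid), dsds_models.get(tid))
                        for s in sites])
            return values

        train_values = score_all(train_sites, "train")
        test_values = score_all(test_sites, "test")

        # Post-processing models fitted on the training half.
        lr_models: dict[tuple[str, str], LRModel] = {}
        pints_models: dict[tuple[str, str], PintsModel] = {}
        for tid, sites in train_sites.items():
            labels = np.array([s.label for s in sites])
            for meas in measurements:
                orient = measurement_orientation(meas)
                if "lr" in postprocessings:
                    lr_models[(tid, meas)] = fit_lr(
                        train_values[(tid, meas)], labels,
                        template_id=tid, orientation=orient)
                if "pints" in postprocessings and orient == "deviation":
                    negs = train_values[(tid, meas)][labels == -1]
                    if negs.size >= 20:
                        pints_models[(tid, meas)] = fit_pints_null(
                            np.sqrt(negs), templates[tid])

        # Single-template evaluation: pooled test sites per template.
        for tid, sites in test_sites.items():
            labels = np.array([s.label for s in sites])
            if not (np.any(labels == 1) and np.any(labels == -1)):
                continue
            for meas in measurements:
                values = test_values[(tid, meas)]
                ranking = values if measurement_orientation(meas) == \
                    "similarity" else -values
                records.append({
                    "analysis": "single", "repeat": plan.repeat,
                    "template_id": tid, "measurement": meas,
                    "postprocessing": "direct",
                    "roc": evaluation.roc_score(ranking, labels),
                    "roc5": evaluation.roc5_score(ranking, labels),
                    "sensitivity": evaluation.sensitivity_at_specificity(
                        ranking, labels),
                })

        # Multiple-template evaluation: per-protein rows across templates.
        by_structure: dict[str, list[tuple[str, int, dict]]] = {}
        for tid, sites in test_sites.items():
            for s, in_values in zip(sites, range(len(sites))):
                entry = (tid, s.label,
                         {meas: test_values[(tid, meas)][in_values]
                          for meas in measurements})
                by_structure.setdefault(s.structure_id, []).append(entry)
        for meas in measurements:
            orient = measurement_orientation(meas)
            for post in postprocessings:
                if post == "pints" and orient != "deviation":
                    continue
                per_protein = {"roc": [], "roc5": [], "sensitivity": []}
                for sid, entries in by_structure.items():
                    labels = np.array([e[1] for e in entries])
                    if not (np.any(labels == 1) and np.any(labels == -1)):
                        continue
                    scores = []
                    usable = True
                    for tid, _, values in entries:
                        raw = values[meas]
                        if post == "direct":
                            conf = raw if orient == "similarity" else -raw
                        elif post == "lr":
                            conf = lr_posterior(lr_models[(tid, meas)], raw)
                        else:
                            model = pints_models.get((tid, meas))
                            if model is None:
                                usable = False
                                break
                            conf = -pints_logF(model, float(np.sqrt(raw)))
                        scores.append(conf)
                    if not usable:
                        continue
                    scores = np.array(scores)
                    per_protein["roc"].append(
                        evaluation.roc_score(scores, labels))
                    per_protein["roc5"].append(
                        evaluation.roc5_score(scores, labels))
                    per_protein["sensitivity"].append(
                        evaluation.sensitivity_at_specificity(scores, labels))
                if per_protein["roc"]:
                    records.append({
                        "analysis": "multiple", "repeat": plan.repeat,
                        "template_id": "(all)", "measurement": meas,
                        "postprocessing": post,
                        "roc": float(np.mean(per_protein["roc"])),
                        "roc5": float(np.mean(per_protein["roc5"])),
                        "sensitivity": float(
                            np.mean(per_protein["sensitivity"])),
                    })
    detail = pd.DataFrame.from_records(records)
    summary = (detail
               .groupby(["analysis", "measurement", "postprocessing"],
                        as_index=False)[["roc", "roc5", "sensitivity"]]
               .mean())
    return summary, {"detail": detail, **audit}
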