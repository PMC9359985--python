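"""Shared model-fitting workflow: cross-validated base-model fits over a
presence/background design, performance-weighted ensemble assembly, and
map-level products (ensemble, committee).

Every (algorithm x CV run) fit becomes an ensemble member, weighted by
its held-out evaluation metric above the no-skill baseline. The ensemble
threshold is re-optimized by max sensitivity+specificity on the
ensemble's calibration scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import models as mdl
from .ensemble import (EnsembleModel, committee_map, ensemble_weights,
                       weighted_average_map)
from .evaluation import auc, evaluate_scores, split_cv
from .grids import CovariateStack, Grid
from .models import FittedModel, ModelAdapter, predict_map
from .occurrences import OccurrenceSet, SampleDesign, build_design

#: default native algorithm set (the four from-scratch members)
DEFAULT_ALGORITHMS = ("glm", "sre", "cta", "gbm")


@dataclass
class FitConfig:
    """Settings for one ensemble fit."""

    variables: tuple[str, ...] | None = None      # None -> all stack variables
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    adapters: tuple[ModelAdapter, ...] = ()
    cv_runs: int = 3
    train_fraction: float = 0.8
    weighting_metric: str = "auc"                 # "auc" or "tss"
    glm_terms: str = "quadratic"
    sre_alpha: float = 0.025
    cta_max_depth: int = 8
    cta_min_node_weight: float = 1.0
    gbm_n_trees: int = 250
    gbm_learning_rate: float = 0.1
    gbm_tree_depth: int = 2

    def baseline(self) -> float:
        # no-skill floor: 0.5 for ROC-type scores, 0 for TSS
        return 0.5 if self.weighting_metric == "auc" else 0.0


def _fit_one(algorithm: str, design: SampleDesign, config: FitConfig
             ) -> FittedModel:
    if algorithm == "glm":
        return mdl.fit_glm(design, terms=config.glm_terms)
    if algorithm == "sre":
        return mdl.fit_sre(design, alpha=config.sre_alpha)
    if algorithm == "cta":
        return mdl.fit_cta(design, max_depth=config.cta_max_depth,
                           min_node_weight=config.cta_min_node_weight)
    if algorithm == "gbm":
        return mdl.fit_gbm(design, n_trees=config.gbm_n_trees,
                           learning_rate=config.gbm_learning_rate,
                           tree_depth=config.gbm_tree_depth)
    for adapter in config.adapters:
        if adapter.name == algorithm:
            return adapter(design)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class EnsembleFit:
    """Everything produced by one cross-validated ensemble fit."""

    ensemble: EnsembleModel
    design: SampleDesign
    member_thresholds: list[float]
    evaluation_table: pd.DataFrame      # one row per (algorithm, run)
    ensemble_scores: dict               # calibration scores of the ensemble
    threshold: float                    # tau_ens

    def mean_internal_auc(self) -> float:
        return float(self.evaluation_table["auc"].mean())

    def predict_maps(self, stack: CovariateStack
                     ) -> tuple[Grid, Grid, list[Grid]]:
        """(ensemble map, committee map, member maps) over a stack."""
        member_maps = [predict_map(m, stack) for m in self.ensemble.members]
        ens_map = weighted_average_map(member_maps, self.ensemble.weights)
        comm_map = committee_map(list(zip(member_maps,
                                          self.member_thresholds)))
        return ens_map, comm_map, member_maps


def fit_ensemble(presences: OccurrenceSet, background: OccurrenceSet,
                 stack: CovariateStack, config: FitConfig, seed: int
                 ) -> EnsembleFit:
    """Cross-validated multi-algorithm ensemble fit.

    For each algorithm and CV run the model is calibrated on the training
    split and evaluated (ROC, TSS, sensitivity, specificity and the
    max-sens/spec threshold) on the held-out split; each such fit joins
    the ensemble with weight proportional to its held-out metric above
    the baseline.
    """
    variables = list(config.variables) if config.variables else stack.names
    design = build_design(presences, background, stack, variables)
    splits = split_cv(design, runs=config.cv_runs,
                      train_fraction=config.train_fraction, seed=seed)

    members: list[FittedModel] = []
    thresholds: list[float] = []
    rows = []
    algorithms = tuple(config.algorithms) + tuple(
        a.name for a in config.adapters if a.name not in config.algorithms)
    for algorithm in algorithms:
        for sp in splits:
            train = design.subset_rows(sp.train_idx)
            test = design.subset_rows(sp.test_idx)
            model = _fit_one(algorithm, train, config)
            test_pred = model.predict(test.X)
            scores = evaluate_scores(test_pred[test.y == 1],
                                     test_pred[test.y == 0])
            model.threshold = scores.threshold
            model.scores = {"run": sp.run, **scores.as_dict()}
            members.append(model)
            thresholds.append(scores.threshold)
            rows.append({"algorithm": algorithm, "run": sp.run,
                         **scores.as_dict()})
    table = pd.DataFrame(rows)

    metric = config.weighting_metric
    member_metric = table[metric].to_numpy()
    weights = ensemble_weights(member_metric, baseline=config.baseline())
    ensemble = EnsembleModel(members, weights, weighting_metric=metric)

    # ensemble calibration scores over the full design
    cal = ensemble.predict(design.X)
    ens_scores = evaluate_scores(cal[design.y == 1], cal[design.y == 0])
    ensemble.threshold = ens_scores.threshold
    ensemble.scores = ens_scores.as_dict()
    return EnsembleFit(ensemble, design, thresholds, table,
                       ens_scores.as_dict(), ens_scores.threshold)
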