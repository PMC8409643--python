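"""End-to-end risk-modeling pipeline.

Order of operations: thin occurrences (2000 m) -> sample background ->
focal-average predictors (450 m) -> extract samples and assign 10 CV folds
-> correlation grouping with univariate winners -> stepwise jackknife
pruning -> 18-combination AICc tuning -> final per-fold refit (mean test
AUC, omission) and full-data fit -> logistic projection -> Boyce-index
classification into a low/moderate/high risk map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import BoyceCurve, RiskMap, boyce_curve, classify_risk
from .config import RunConfig
from .io import PointSet, PredictorStack, Raster
from .maxent import FeatureSpec, MaxentModel, expand_features, fit_maxent, project
from .prep import (
    SampleTable,
    ThinResult,
    assign_folds,
    build_sample_table,
    sample_background,
    smooth_stack,
    thin_occurrences,
)
from .selection import (
    CVEvaluator,
    SelectionTrace,
    TuningResult,
    group_correlated,
    stepwise_jackknife,
    tune_hyperparameters,
    univariate_select,
    variable_importance,
)
from .synthetic import LandscapeConfig, SyntheticTruth, simulate

logger = logging.getLogger("growrisk")


@dataclass
class PipelineResult:
    config: RunConfig
    smoothed: PredictorStack
    thin: ThinResult
    background: PointSet
    table: SampleTable
    groups: list
    selected: list[str]
    trace: SelectionTrace
    tuning: TuningResult
    fold_metrics: pd.DataFrame
    final_model: MaxentModel
    logistic_map: Raster
    boyce: BoyceCurve
    riskmap: RiskMap
    importance: pd.DataFrame
    truth: SyntheticTruth | None = None

    @property
    def mean_test_auc(self) -> float:
        return float(self.fold_metrics["test_auc"].mean())

    @property
    def mean_omission(self) -> float:
        return float(self.fold_metrics["omission_10pct"].mean())


def run_pipeline(stack: PredictorStack, presences: PointSet,
                 config: RunConfig | None = None,
                 truth: SyntheticTruth | None = None) -> PipelineResult:
    """Run the full modeling pipeline on a predictor stack and occurrences."""
    config = config or RunConfig()
    ss = np.random.SeedSequence(config.seed)
    seed_thin, seed_bg, seed_fold, seed_imp = ss.spawn(4)

    thin = thin_occurrences(presences, config.thin_distance,
                            seed=np.random.default_rng(seed_thin))
    smoothed = smooth_stack(stack, config.focal_radius)
    mask = Raster(smoothed.grid, smoothed.combined_valid().astype(float))
    background = sample_background(mask, config.n_background,
                                   seed=np.random.default_rng(seed_bg))
    table = build_sample_table(smoothed, thin.kept, background)
    table = assign_folds(table, k=config.cv_folds,
                         seed=np.random.default_rng(seed_fold))

    spec = FeatureSpec(mode="auto", n_hinge_knots=config.n_hinge_knots)
    evaluator = CVEvaluator(table, spec=spec, max_iter=config.max_iterations)
    groups = group_correlated(table, threshold=config.correlation_threshold)
    selected = univariate_select(groups, table, evaluator)
    logger.info("pipeline: %d variables after correlation grouping", len(selected))

    trace = stepwise_jackknife(selected, evaluator)
    logger.info("pipeline: retained %s (mean test AUC %.3f)",
                trace.retained, trace.retained_auc)

    tuning = tune_hyperparameters(
        table, trace.retained, smoothed,
        modes=config.feature_modes, multipliers=config.reg_multipliers,
        n_hinge_knots=config.n_hinge_knots, max_iter=config.max_iterations,
    )
    mode, mult = tuning.winner
    logger.info("pipeline: tuned settings mode=%s multiplier=%.2f", mode, mult)

    if mode == "auto":
        final_eval = evaluator
    else:
        final_eval = CVEvaluator(
            table, spec=FeatureSpec(mode=mode, n_hinge_knots=config.n_hinge_knots),
            max_iter=config.max_iterations,
        )
    fold_metrics = final_eval.fold_metrics(trace.retained, r=mult)

    var_idx = [table.variables.index(v) for v in trace.retained]
    fm = expand_features(
        table.values("presence")[:, var_idx],
        table.values("background")[:, var_idx],
        trace.retained,
        FeatureSpec(mode=mode, n_hinge_knots=config.n_hinge_knots),
    )
    final_model = fit_maxent(fm, r=mult, max_iter=config.max_iterations)

    logistic_map = project(final_model, smoothed, output="logistic")
    curve = boyce_curve(logistic_map, thin.kept)
    riskmap = classify_risk(logistic_map, curve, source_model="final")
    importance = variable_importance(final_model, table,
                                     seed=np.random.default_rng(seed_imp))

    return PipelineResult(
        config=config, smoothed=smoothed, thin=thin, background=background,
        table=table, groups=groups, selected=selected, trace=trace,
        tuning=tuning, fold_metrics=fold_metrics, final_model=final_model,
        logistic_map=logistic_map, boyce=curve, riskmap=riskmap,
        importance=importance, truth=truth,
    )


def run_synthetic_pipeline(landscape: LandscapeConfig | None = None,
                           config: RunConfig | None = None) -> PipelineResult:
    """Simulate the default synthetic landscape and run the pipeline on it."""
    from .config import desk_preset

    landscape = landscape or LandscapeConfig()
    config = config or desk_preset(seed=landscape.seed)
    truth = simulate(landscape)
    return run_pipeline(truth.stack, truth.presence_points, config, truth=truth)
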