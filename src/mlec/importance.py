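"""Driver-importance attribution for the constrained projections.

Two tasks:

* historical drivers — how much each observed historical variable shapes the
  projected future fire distribution, via per-feature permutation importance
  for the tree learners and leave-one-covariate-out (LOCO) retraining for the
  kernel learner, reduced to variable level by taking the maximum over a
  variable's 13 encodings;
* trend attribution — how much each driver's projected (optionally
  observation-constrained) trend explains the projected emission trend over a
  selected set of cells, with the same learners trained on per-cell trends.

Scores are floored at zero and standardized to sum to 100 per algorithm; the
reported table also carries the cross-algorithm mean.  Raw (unfloored)
values are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation

from ._rng import child_seed
from .constrain import MLTConfig, TrainedConstraint, tune_and_train
from .estimators import ALGORITHMS
from .features import TrainingTable
from .grid import Field
from .synthetic import DYNAMIC_VARIABLES, STATIC_VARIABLES, SyntheticWorld

__all__ = [
    "ImportanceTable",
    "permutation_importance",
    "loco_importance",
    "variable_level_importance",
    "historical_driver_importance",
    "trend_attribution",
]


@dataclass
class ImportanceTable:
    task: str
    per_algorithm: pd.DataFrame  # index variable, columns algorithms (standardized, sum 100)
    mean: pd.Series  # cross-algorithm mean per variable
    raw: pd.DataFrame  # unfloored raw scores
    seed: int

    def top_variable(self) -> str:
        return str(self.mean.idxmax())


def _standardize(scores: pd.Series) -> pd.Series:
    floored = scores.clip(lower=0.0)
    total = floored.sum()
    if total == 0:
        return floored * 0.0
    return floored / total * 100.0


def permutation_importance(
    trained: TrainedConstraint,
    table: TrainingTable,
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.Series:
    """Per-feature RMSE increase under permutation, standardized to sum 100."""
    res = _sk_permutation(
        trained.model,
        table.X,
        table.y,
        scoring="neg_root_mean_squared_error",
        n_repeats=n_repeats,
        random_state=child_seed(seed, "perm") % (2**32),
        n_jobs=1,
    )
    names = [f"{v}.{e}" for v, e in table.feature_meta]
    return _standardize(pd.Series(res.importances_mean, index=names))


def loco_importance(
    table: TrainingTable,
    config: MLTConfig,
    seed: int = 0,
    full: TrainedConstraint | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Leave-one-covariate-out marginal contributions per variable.

    Contribution of v = CV RMSE without v minus CV RMSE of the full model
    (the error increase caused by removing it); returns (standardized, raw).
    """
    variables = sorted({v for v, _ in table.feature_meta})
    if len(variables) < 2:
        raise ValueError("LOCO needs at least 2 variables")
    if full is None:
        full = tune_and_train(table, config)
    raw = {}
    for var in variables:
        reduced = tune_and_train(table.without_variable(var), config)
        raw[var] = reduced.cv_rmse - full.cv_rmse
    raw = pd.Series(raw)
    return _standardize(raw), raw


def variable_level_importance(
    feature_scores: Mapping[str, pd.Series],
    grouping: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Reduce per-feature scores to variables and average across algorithms.

    ``feature_scores`` maps algorithm name to a per-feature (or already
    per-variable) score Series; ``grouping`` maps feature name to variable
    (defaults to splitting at the last '.').  A variable's score is the
    maximum over its encodings, re-standardized to sum 100 per algorithm.
    """
    per_alg = {}
    for alg, scores in feature_scores.items():
        if grouping is None:
            groups = {name: name.rsplit(".", 1)[0] if "." in name else name for name in scores.index}
        else:
            missing = [n for n in scores.index if n not in grouping]
            if missing:
                raise KeyError(f"features without a variable group: {missing}")
            groups = grouping
        by_var = scores.groupby(scores.index.map(groups.get)).max()
        per_alg[alg] = _standardize(by_var)
    df = pd.DataFrame(per_alg).fillna(0.0)
    return df, df.mean(axis=1)


def historical_driver_importance(
    tables: Mapping[str, TrainingTable] | TrainingTable,
    configs: Mapping[str, MLTConfig],
    trained: Mapping[str, TrainedConstraint] | None = None,
    seed: int = 0,
    n_repeats: int = 5,
) -> ImportanceTable:
    """Task 1: importance of each historical driver for the projection.

    Tree learners (random forest, gbm) use permutation importance; the kernel
    learner uses LOCO.  ``tables`` may be one table shared by all algorithms.
    """
    scores: dict[str, pd.Series] = {}
    raws: dict[str, pd.Series] = {}
    for alg, cfg in configs.items():
        table = tables[alg] if isinstance(tables, Mapping) else tables
        fit = (trained or {}).get(alg) or tune_and_train(table, cfg)
        if alg == "svm_rbf":
            std, raw = loco_importance(table, cfg, seed=seed, full=fit)
            scores[alg] = std
            raws[alg] = raw
        else:
            per_feature = permutation_importance(fit, table, seed=seed, n_repeats=n_repeats)
            scores[alg] = per_feature
            raws[alg] = per_feature
    per_alg, mean = variable_level_importance(scores)

    def _group_max(s: pd.Series) -> pd.Series:
        groups = {n: n.rsplit(".", 1)[0] if "." in n else n for n in s.index}
        return s.groupby(s.index.map(groups.get)).max()

    raw_df = pd.DataFrame({a: _group_max(r) for a, r in raws.items()}).fillna(0.0)
    return ImportanceTable("historical_drivers", per_alg, mean, raw_df, seed)


# ---------------------------------------------------------------------------
# task 2: trend attribution


def _trend_of(fields: Sequence[Field]) -> np.ndarray:
    stack = np.stack([f.values for f in fields])
    x = np.arange(stack.shape[0], dtype=float)
    xc = x - x.mean()
    return np.tensordot(xc, stack - stack.mean(axis=0), axes=(0, 0)) / np.sum(xc**2)


def trend_attribution(
    world: SyntheticWorld,
    ensemble_kind: str = "default",
    selector: np.ndarray | None = None,
    configs: Mapping[str, MLTConfig] | None = None,
    seed: int = 0,
    n_repeats: int = 5,
    constrained_driver_trends: Mapping[str, np.ndarray] | None = None,
    constrained_emission_trend: np.ndarray | None = None,
) -> ImportanceTable:
    """Task 2: importance of driver trends for the projected emission trend.

    Trains the learners to predict the per-cell emission trend from per-cell
    driver trends over the selected cells.  Flash rate and orography are
    excluded (static); socio trends are prescribed, never constrained.  For
    ``ensemble_kind="constrained"`` pass trends of the constrained fields
    (see :func:`mlec.pipeline` helpers); the default kind uses the
    multimodel-mean simulated trends.
    """
    cfg = world.config
    decades = list(cfg.decades)
    mask = world.land_mask if selector is None else (world.land_mask & np.asarray(selector, bool))
    if mask.sum() < 50:
        raise ValueError(f"selector keeps only {int(mask.sum())} cells; need at least 50")

    driver_vars = [v for v in DYNAMIC_VARIABLES if v != "fire_carbon_emission"]
    socio_vars = ["land_use", "population"]

    trends: dict[str, np.ndarray] = {}
    if ensemble_kind == "constrained" and constrained_driver_trends is not None:
        trends.update({k: np.asarray(v) for k, v in constrained_driver_trends.items()})
    for var in driver_vars:
        if var in trends:
            continue
        if ensemble_kind == "default":
            per_member = [
                _trend_of([world.member_drivers[i][var][d] for d in decades])
                for i in range(cfg.n_models)
            ]
            trends[var] = np.mean(per_member, axis=0)
        else:
            trends[var] = _trend_of([world.truth_drivers[var][d] for d in decades])
    trends["land_use"] = _trend_of([world.truth_drivers["land_use"][d] for d in decades])
    trends["population"] = _trend_of([world.socio["population"][d] for d in decades])

    if ensemble_kind == "constrained" and constrained_emission_trend is not None:
        y_grid = np.asarray(constrained_emission_trend)
    elif ensemble_kind == "default":
        per_member = [
            _trend_of([world.member_emission[i][d] for d in decades]) for i in range(cfg.n_models)
        ]
        y_grid = np.mean(per_member, axis=0)
    else:
        y_grid = _trend_of([world.truth_emission[d] for d in decades])

    y = y_grid[mask]
    if np.std(y) == 0:
        warnings.warn("degenerate emission trend (zero variance); no attribution possible")
        empty = pd.DataFrame()
        return ImportanceTable("trend_attribution", empty, pd.Series(dtype=float), empty, seed)

    variables = driver_vars + socio_vars
    X = np.column_stack([trends[v][mask] for v in variables])
    meta = [(v, "static") for v in variables]
    coords = np.zeros((X.shape[0], 2))
    table = TrainingTable(X, y, meta, coords, f"trend:{ensemble_kind}")

    if configs is None:
        configs = {a: MLTConfig(algorithm=a, seed=child_seed(seed, "trend", a)) for a in ALGORITHMS}
    scores: dict[str, pd.Series] = {}
    raws: dict[str, pd.Series] = {}
    for alg, mcfg in configs.items():
        fit = tune_and_train(table, mcfg)
        if alg == "svm_rbf":
            std, raw = loco_importance(table, mcfg, seed=seed, full=fit)
        else:
            per_feature = permutation_importance(fit, table, seed=seed, n_repeats=n_repeats)
            per_feature.index = [n.rsplit(".", 1)[0] for n in per_feature.index]
            std, raw = per_feature, per_feature
        scores[alg] = std
        raws[alg] = raw
    per_alg = pd.DataFrame({a: _standardize(s) for a, s in scores.items()}).fillna(0.0)
    return ImportanceTable(
        "trend_attribution", per_alg, per_alg.mean(axis=1), pd.DataFrame(raws).fillna(0.0), seed
    )


def constrain_driver_trends(
    world: SyntheticWorld,
    variables: Sequence[str],
    algorithms: Sequence[str] = ("gbm",),
    sources: Sequence = ("multimodel_mean",),
    decades: Sequence[str] | None = None,
    combination_cap: int = 1,
    mlt_overrides: Mapping | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Observation-constrain each driver's annual mean per decade, then take trends.

    Only annual means are constrained.  Returns per-variable per-cell trend
    arrays for use as the ``constrained_driver_trends`` of
    :func:`trend_attribution`.
    """
    from .features import PredictorSpec, build_observation_matrix, build_training_table
    from .constrain import predict_field

    cfg = world.config
    hist = world.hist_decade
    decades = list(decades) if decades is not None else list(cfg.decades)
    pspec = PredictorSpec(
        dynamic_variables=DYNAMIC_VARIABLES,
        static_variables=STATIC_VARIABLES,
        historical_decade=hist,
    )
    obs_mats = build_observation_matrix(
        world.observations, pspec, world.land_mask, cap=combination_cap,
        seed=child_seed(seed, "driver-combos"),
    )
    out: dict[str, np.ndarray] = {}
    for var in variables:
        per_decade = []
        for decade in decades:
            preds = []
            for source in sources:
                predictors = world.predictor_fields(source, hist)
                if source == "multimodel_mean":
                    target_vals = np.mean(
                        [world.member_drivers[i][var][decade].values for i in range(cfg.n_models)],
                        axis=0,
                    )
                    target = world.truth_drivers[var][decade].copy_with(values=target_vals)
                elif source == "truth":
                    target = world.truth_drivers[var][decade]
                else:
                    target = world.member_drivers[int(source)][var][decade]
                table = build_training_table(predictors, target, pspec, world.land_mask, str(source))
                for alg in algorithms:
                    mcfg = MLTConfig(
                        algorithm=alg,
                        seed=child_seed(seed, "driver", var, decade, source, alg),
                        **(dict(mlt_overrides or {}).get(alg, {})),
                    )
                    trained = tune_and_train(table, mcfg, decade)
                    for X_obs, _ in obs_mats:
                        f = trained.model.predict(X_obs)
                        grid = np.zeros(world.land_mask.shape)
                        grid[world.land_mask] = f
                        preds.append(grid)
            per_decade.append(np.mean(preds, axis=0))
        stack = np.stack(per_decade)
        x = np.arange(stack.shape[0], dtype=float)
        xc = x - x.mean()
        out[var] = np.tensordot(xc, stack - stack.mean(axis=0), axes=(0, 0)) / np.sum(xc**2)
    return out
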