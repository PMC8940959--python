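"""Train the learners per (source, target decade) and constrain the ensemble.

For each pseudo-model (and the multimodel mean), each algorithm is tuned and
trained on that source's spatial sample mapping historical predictors to
future fire carbon emission; feeding the observed historical predictors into
the trained learner yields one observation-constrained member field per
(source, observation-dataset combination, algorithm, decade).  The member
axis is flattened before computing the ensemble mean and percentile bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._rng import child_seed
from .estimators import ALGORITHMS, ConstraintModel
from .features import PredictorSpec, TrainingTable, build_observation_matrix, build_training_table
from .grid import Field, GridSpec
from .synthetic import DYNAMIC_VARIABLES, STATIC_VARIABLES, SyntheticWorld

__all__ = [
    "MLTConfig",
    "TrainedConstraint",
    "ConstrainedEnsemble",
    "tune_and_train",
    "predict_field",
    "run_constraint",
    "aggregate",
]

PERCENTILES = (10, 25, 50, 75, 90)


def fast_mlt_overrides() -> dict:
    """Desk-scale hyperparameter grids for full-pipeline runs.

    The full canonical grids (mtry 5..50 step 1, 30 SVR costs, tree counts
    10..200 step 5) remain the :class:`MLTConfig` defaults; these thinned
    grids keep an end-to-end multi-source run within minutes on one CPU
    while preserving each algorithm's tuning axis.
    """
    return {
        "random_forest": {"rf_mtry": (5, 25, 45), "rf_n_trees": 50},
        "gbm": {"gbm_tree_counts": (25, 50)},
        "svm_rbf": {"svm_n_costs": 30},
    }


@dataclass
class MLTConfig:
    """Hyperparameter search configuration for one algorithm."""

    algorithm: str = "random_forest"
    k_folds: int = 10
    seed: int = 0
    rf_mtry: Sequence[int] | None = None  # default 5..50 step 1
    rf_n_trees: int = 100
    gbm_tree_counts: Sequence[int] | None = None  # default 10..200 step 5
    svm_n_costs: int = 30

    def make_estimator(self) -> ConstraintModel:
        return ConstraintModel(
            algorithm=self.algorithm,
            n_folds=self.k_folds,
            seed=self.seed,
            rf_mtry=self.rf_mtry,
            rf_n_trees=self.rf_n_trees,
            gbm_tree_counts=self.gbm_tree_counts,
            svm_n_costs=self.svm_n_costs,
        )


@dataclass
class TrainedConstraint:
    """One tuned learner for one (source, target decade)."""

    algorithm: str
    best_params: dict
    cv_rmse: float
    cv_r2: float
    model: ConstraintModel
    feature_meta: list
    source: str
    target_decade: str
    seed: int


def tune_and_train(table: TrainingTable, config: MLTConfig, target_decade: str = "") -> TrainedConstraint:
    """Grid search with shared folds, refit on the full sample."""
    est = config.make_estimator().fit(table.X, table.y)
    return TrainedConstraint(
        algorithm=config.algorithm,
        best_params=est.best_params_,
        cv_rmse=est.cv_rmse_,
        cv_r2=est.cv_r2_,
        model=est,
        feature_meta=list(table.feature_meta),
        source=table.provenance,
        target_decade=target_decade,
        seed=config.seed,
    )


def predict_field(
    trained: TrainedConstraint,
    X_obs: np.ndarray,
    spec: GridSpec,
    mask: np.ndarray,
    feature_meta: Sequence | None = None,
) -> Field:
    """Predictions written back to the unmasked cells; negatives clipped to 0."""
    if feature_meta is not None:
        have = [tuple(m) for m in feature_meta]
        want = [tuple(m) for m in trained.feature_meta]
        if have != want:
            missing = [m for m in want if m not in have]
            extra = [m for m in have if m not in want]
            raise ValueError(f"feature mismatch: missing {missing}, unexpected {extra}")
    mask = np.asarray(mask, dtype=bool)
    if X_obs.shape != (int(mask.sum()), len(trained.feature_meta)):
        raise ValueError(
            f"X_obs shape {X_obs.shape} does not match "
            f"({int(mask.sum())}, {len(trained.feature_meta)})"
        )
    pred = np.clip(trained.model.predict(X_obs), 0.0, None)
    values = np.zeros(mask.shape)
    values[mask] = pred
    return Field(spec, values, mask, "fire_carbon_emission", "kg m-2 yr-1", trained.target_decade)


@dataclass
class ConstrainedEnsemble:
    """Predicted fields indexed by (source, combination, algorithm, decade)."""

    members: dict  # (source, combo_label, algorithm, decade) -> Field
    training_log: list  # per (source, algorithm, decade) CV metrics
    decades: tuple

    def member_fields(self, decade: str) -> list[Field]:
        return [f for (s, c, a, d), f in self.members.items() if d == decade]

    def mean_field(self, decade: str) -> Field:
        return aggregate(self.member_fields(decade))["mean"]

    def percentile_field(self, decade: str, q: int) -> Field:
        return aggregate(self.member_fields(decade))[f"p{q}"]


def aggregate(members: Sequence[Field]) -> dict[str, Field]:
    """Per-cell mean and percentiles over the flattened member axis."""
    if len(members) == 0:
        raise ValueError("cannot aggregate an empty member set")
    ref = members[0]
    stack = np.stack([f.values for f in members])
    out = {"mean": ref.copy_with(values=stack.mean(axis=0))}
    qs = np.percentile(stack, PERCENTILES, axis=0)
    for q, vals in zip(PERCENTILES, qs):
        out[f"p{q}"] = ref.copy_with(values=vals)
    return out


def _predictor_spec(target_decade: str, hist_decade: str) -> PredictorSpec:
    return PredictorSpec(
        dynamic_variables=DYNAMIC_VARIABLES,
        static_variables=STATIC_VARIABLES,
        historical_decade=hist_decade,
        target_decade=target_decade,
    )


def run_constraint(
    world: SyntheticWorld,
    decades: Sequence[str] | None = None,
    algorithms: Sequence[str] = ALGORITHMS,
    sources: Sequence | None = None,
    combination_cap: int = 8,
    mlt_overrides: Mapping | None = None,
    seed: int = 0,
    training_spec: GridSpec | None = None,
) -> ConstrainedEnsemble:
    """Full observational constraint on a (synthetic or user-supplied) world.

    ``training_spec`` optionally regrids the training fields to a coarser
    resolution before building tables (resolution-sensitivity experiments);
    observations are always fed at their native resolution.
    """
    from .grid import regrid_bilinear

    cfg = world.config
    hist = world.hist_decade
    decades = tuple(decades) if decades is not None else tuple(cfg.decades[1:])
    sources = list(sources) if sources is not None else list(range(cfg.n_models))
    mlt_overrides = dict(mlt_overrides or {})

    obs_mats = build_observation_matrix(
        world.observations, _predictor_spec(decades[0], hist), world.land_mask,
        cap=combination_cap, seed=child_seed(seed, "combos"),
    )
    members: dict = {}
    log: list = []
    for source in sources:
        predictors = world.predictor_fields(source, hist)
        if training_spec is not None:
            predictors = _regrid_predictor_set(predictors, training_spec)
        train_mask = next(iter(predictors.values()))["annual"].mask
        for decade in decades:
            pspec = _predictor_spec(decade, hist)
            target = world.target_emission(source, decade)
            if training_spec is not None:
                target = regrid_bilinear(target, training_spec)
            table = build_training_table(predictors, target, pspec, train_mask, str(source))
            for algorithm in algorithms:
                mcfg = MLTConfig(
                    algorithm=algorithm,
                    seed=child_seed(seed, source, decade, algorithm),
                    **mlt_overrides.get(algorithm, {}),
                )
                trained = tune_and_train(table, mcfg, decade)
                log.append(
                    {
                        "source": str(source),
                        "decade": decade,
                        "algorithm": algorithm,
                        "cv_rmse": trained.cv_rmse,
                        "cv_r2": trained.cv_r2,
                        "best_params": trained.best_params,
                        "seed": mcfg.seed,
                    }
                )
                for X_obs, label in obs_mats:
                    field = predict_field(trained, X_obs, world.spec, world.land_mask)
                    field.time_tag = decade
                    members[(str(source), label, algorithm, decade)] = field
    return ConstrainedEnsemble(members=members, training_log=log, decades=decades)


def _regrid_predictor_set(predictors: Mapping, target: GridSpec) -> dict:
    from .grid import regrid_bilinear

    out: dict = {}
    for var, entry in predictors.items():
        annual = regrid_bilinear(entry["annual"], target)
        monthly = None
        if entry["monthly"] is not None:
            monthly = [regrid_bilinear(f, target) for f in entry["monthly"]]
        out[var] = {"annual": annual, "monthly": monthly}
    return out
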