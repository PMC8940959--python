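"""End-to-end orchestration with a reproducibility manifest.

A run is configured by a plain-YAML mapping (see :class:`RunConfig`), seeds
are derived per stage from one root seed, and every artifact written is
checksummed into the manifest so a rerun with the same config is
bit-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as _dfield
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import child_seed
from .constrain import run_constraint
from .diagnostics import decadal_trend_fields, holdout_validation, sign_agreement_mask
from .estimators import ALGORITHMS
from .exposure import exposure_series, rank_countries
from .grid import GridSpec, save_field, save_region_map
from .importance import historical_driver_importance, trend_attribution
from .synthetic import SOCIO_METRICS, WorldConfig, generate_world

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]

_STAGES = ("simulate", "constrain", "validate", "trends", "exposure", "importance")


@dataclass
class RunConfig:
    out_dir: str = "mlec_run"
    seed: int = 0
    resolution: float = 5.0
    n_models: int = 8
    n_obs_datasets: int = 2
    scenario: str = "synthetic-ssp585"
    algorithms: Sequence[str] = ALGORITHMS
    decades: Sequence[str] | None = None  # default: world's future decades
    combination_cap: int = 8
    stages: Sequence[str] = _STAGES
    mlt_overrides: Mapping = _dfield(default_factory=dict)
    world_overrides: Mapping = _dfield(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {_STAGES}")
        bad = [a for a in self.algorithms if a not in ALGORITHMS]
        if bad:
            raise ValueError(f"unknown algorithms {bad}; valid: {ALGORITHMS}")

    def world_config(self) -> WorldConfig:
        return WorldConfig(
            spec=GridSpec.global_grid(self.resolution),
            n_models=self.n_models,
            n_obs_datasets=self.n_obs_datasets,
            seed=child_seed(self.seed, "world"),
            **dict(self.world_overrides),
        )


@dataclass
class RunManifest:
    config: dict
    stages: dict  # stage -> {seed, seconds, outputs: {path: sha256}}
    status: str = "ok"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"config": self.config, "stages": self.stages, "status": self.status}, indent=2, default=str))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValueError(f"invalid run config: {exc}") from None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), stages={})
    marker = out / "FAILED"

    def record(stage: str, seed: int, t0: float, paths: list[Path]) -> None:
        manifest.stages[stage] = {
            "seed": seed,
            "seconds": round(time.time() - t0, 2),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in paths},
        }

    world = None
    ensemble = None
    try:
        if "simulate" in config.stages or set(config.stages) & set(_STAGES[1:]):
            t0, seed = time.time(), child_seed(config.seed, "world")
            world = generate_world(config.world_config())
            paths = []
            if "simulate" in config.stages:
                p_truth = out / "truth_emission_hist.nc"
                save_field(world.truth_emission[world.hist_decade], p_truth)
                p_reg = out / "regions.nc"
                p_csv = out / "regions.csv"
                save_region_map(world.regions, p_reg, p_csv)
                paths = [p_truth, p_reg, p_csv]
            record("simulate", seed, t0, paths)

        decades = tuple(config.decades) if config.decades else tuple(world.config.decades[1:])
        if "constrain" in config.stages or "trends" in config.stages or "exposure" in config.stages:
            t0, seed = time.time(), child_seed(config.seed, "constrain")
            ensemble = run_constraint(
                world,
                decades=decades,
                algorithms=config.algorithms,
                combination_cap=config.combination_cap,
                mlt_overrides=config.mlt_overrides,
                seed=seed,
            )
            paths = []
            if "constrain" in config.stages:
                log_path = out / "training_log.csv"
                pd.DataFrame(ensemble.training_log).to_csv(log_path, index=False)
                paths.append(log_path)
                for decade in decades:
                    p = out / f"constrained_mean_{decade}.nc"
                    save_field(ensemble.mean_field(decade), p)
                    paths.append(p)
            record("constrain", seed, t0, paths)

        if "validate" in config.stages:
            t0, seed = time.time(), child_seed(config.seed, "validate")
            report = holdout_validation(
                world,
                algorithms=config.algorithms,
                combination_cap=config.combination_cap,
                mlt_overrides=config.mlt_overrides,
                seed=seed,
                ensemble=ensemble if (ensemble is not None and decades and decades[0] == world.config.decades[1]) else None,
            )
            p = out / "validation.json"
            p.write_text(json.dumps(report.as_dict(), indent=2))
            record("validate", seed, t0, [p])

        if "trends" in config.stages:
            t0, seed = time.time(), child_seed(config.seed, "trends")
            mean_fields = [ensemble.mean_field(d) for d in decades]
            abs_t, rel_t = decadal_trend_fields(mean_fields, baseline_index=0)
            member_trends = []
            for i in range(world.config.n_models):
                series = [world.member_emission[i][d] for d in decades]
                member_trends.append(decadal_trend_fields(series, baseline_index=0)[0])
            agree = sign_agreement_mask(member_trends)
            p1, p2, p3 = out / "trend_abs.nc", out / "trend_rel.nc", out / "trend_agreement.nc"
            save_field(abs_t, p1)
            save_field(rel_t, p2)
            save_field(agree, p3)
            record("trends", seed, t0, [p1, p2, p3])

        if "exposure" in config.stages:
            t0, seed = time.time(), child_seed(config.seed, "exposure")
            emissions = {d: ensemble.mean_field(d) for d in decades}
            paths = []
            for metric in SOCIO_METRICS:
                socio = {d: world.socio[metric][d] for d in decades}
                series = exposure_series(emissions, socio, world.regions, metric, baseline_index=0)
                table = pd.DataFrame(
                    {
                        "id": series.region_totals.index,
                        "name": [series.region_names.get(int(i), "?") for i in series.region_totals.index],
                        "relative_trend_pct_per_decade": series.region_relative_trends,
                    }
                )
                table["rank"] = table["id"].isin(rank_countries(series, n=10))
                p = out / f"exposure_{metric}.csv"
                table.to_csv(p, index=False)
                paths.append(p)
            record("exposure", seed, t0, paths)

        if "importance" in config.stages:
            t0, seed = time.time(), child_seed(config.seed, "importance")
            from .constrain import MLTConfig, _predictor_spec
            from .features import build_training_table

            predictors = world.predictor_fields("multimodel_mean", world.hist_decade)
            pspec = _predictor_spec(decades[0], world.hist_decade)
            target = world.target_emission("multimodel_mean", decades[0])
            table = build_training_table(predictors, target, pspec, world.land_mask, "multimodel_mean")
            configs = {
                a: MLTConfig(algorithm=a, seed=child_seed(seed, "task1", a), **dict(config.mlt_overrides).get(a, {}))
                for a in config.algorithms
            }
            task1 = historical_driver_importance(table, configs, seed=seed)
            task2 = trend_attribution(world, "default", configs=configs, seed=seed)
            p1, p2 = out / "importance_historical.csv", out / "importance_trend.csv"
            task1.per_algorithm.assign(mean=task1.mean).to_csv(p1)
            task2.per_algorithm.assign(mean=task2.mean).to_csv(p2)
            record("importance", seed, t0, [p1, p2])
    except Exception as exc:
        manifest.status = f"FAILED in stage: {exc}"
        marker.write_text(str(exc))
        manifest.save(out / "manifest.json")
        raise
    if marker.exists():
        marker.unlink()
    manifest.save(out / "manifest.json")
    return manifest
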