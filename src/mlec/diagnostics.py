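"""Validation metrics, decadal trends, robustness masks and hold-out scoring.

RMSE and spatial R^2 are computed unweighted over the unmasked spatial
sample, matching a training objective defined on that same sample; an
area-weighted variant is available behind a flag.  Trends are OLS slopes over
decade index, and relative trends divide by the 2010s (second-decade) value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._rng import child_seed
from .estimators import ALGORITHMS
from .grid import Field, GridSpec, cell_areas
from .linear_ec import gridwise_linear_ec
from .synthetic import SyntheticWorld

__all__ = [
    "rmse",
    "spatial_r2",
    "decadal_trend",
    "decadal_trend_fields",
    "sign_agreement_mask",
    "ValidationReport",
    "holdout_validation",
    "resolution_sweep",
]


def _joint(a: Field, b: Field) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if a.spec != b.spec:
        raise ValueError("fields are on different grids")
    mask = a.mask & b.mask
    if not mask.any():
        raise ValueError("empty joint mask")
    return a.values[mask], b.values[mask], mask


def rmse(a: Field, b: Field, area_weighted: bool = False) -> float:
    """Root-mean-square difference over the joint unmasked sample."""
    va, vb, mask = _joint(a, b)
    d2 = (va - vb) ** 2
    if area_weighted:
        w = cell_areas(a.spec)[mask]
        return float(np.sqrt(np.sum(w * d2) / np.sum(w)))
    return float(np.sqrt(np.mean(d2)))


def spatial_r2(a: Field, b: Field, area_weighted: bool = False) -> float:
    """Squared Pearson spatial correlation over the joint unmasked sample."""
    va, vb, mask = _joint(a, b)
    if area_weighted:
        w = cell_areas(a.spec)[mask]
        w = w / w.sum()
        va = va - np.sum(w * va)
        vb = vb - np.sum(w * vb)
        cov = np.sum(w * va * vb)
        sa = np.sqrt(np.sum(w * va**2))
        sb = np.sqrt(np.sum(w * vb**2))
    else:
        va = va - va.mean()
        vb = vb - vb.mean()
        cov = np.mean(va * vb)
        sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        raise ValueError("spatial correlation undefined for a constant field")
    return float((cov / (sa * sb)) ** 2)


def decadal_trend(
    series: Sequence[float] | np.ndarray,
    baseline_index: int = 1,
    estimator: str = "ols",
) -> dict:
    """Absolute (per decade) and relative (% per decade) trend of a series.

    The relative trend divides the slope by the value at ``baseline_index``
    (the 2010s for a 2010s..2090s series).  ``estimator`` is "ols" (default)
    or "endpoint" (last minus first over the span).
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 decades for a trend")
    x = np.arange(y.size, dtype=float)
    if estimator == "ols":
        slope = float(np.polyfit(x, y, 1)[0])
    elif estimator == "endpoint":
        slope = float((y[-1] - y[0]) / (y.size - 1))
    else:
        raise ValueError("estimator must be 'ols' or 'endpoint'")
    base = y[baseline_index]
    rel = float(slope / base * 100.0) if base != 0 else np.nan
    return {"absolute": slope, "relative_pct": rel}


def decadal_trend_fields(
    fields: Sequence[Field],
    baseline_index: int = 1,
    estimator: str = "ols",
) -> tuple[Field, Field]:
    """Per-cell absolute and relative trends of a decadal field series.

    Cells with a zero baseline get NaN relative trend and are dropped from
    the relative-trend mask.
    """
    ref = fields[0]
    stack = np.stack([f.values for f in fields])
    t = stack.shape[0]
    if t < 3:
        raise ValueError("need at least 3 decades for a trend")
    x = np.arange(t, dtype=float)
    if estimator == "ols":
        xc = x - x.mean()
        slope = np.tensordot(xc, stack - stack.mean(axis=0), axes=(0, 0)) / np.sum(xc**2)
    elif estimator == "endpoint":
        slope = (stack[-1] - stack[0]) / (t - 1)
    else:
        raise ValueError("estimator must be 'ols' or 'endpoint'")
    base = stack[baseline_index]
    ok = base != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(ok, slope / np.where(ok, base, 1.0) * 100.0, np.nan)
    abs_field = ref.copy_with(values=slope, units=f"{ref.units} decade-1", time_tag="trend")
    rel_field = ref.copy_with(
        values=np.where(ok, rel, 0.0), mask=ref.mask & ok,
        units="% decade-1", time_tag="trend",
    )
    return abs_field, rel_field


def sign_agreement_mask(member_trends: Sequence[Field], threshold: float = 0.8) -> Field:
    """True where at least ``threshold`` of members agree on the trend sign.

    Exact zeros count with neither sign; the share is taken over all members.
    """
    if len(member_trends) < 2:
        raise ValueError("need at least 2 members")
    ref = member_trends[0]
    signs = np.stack([np.sign(f.values) for f in member_trends])
    n = signs.shape[0]
    n_pos = (signs > 0).sum(axis=0)
    n_neg = (signs < 0).sum(axis=0)
    share = np.maximum(n_pos, n_neg) / n
    return ref.copy_with(values=(share >= threshold).astype(float), units="1", time_tag="agreement")


# ---------------------------------------------------------------------------
# hold-out validation orchestration


@dataclass
class ValidationReport:
    """Scores of the default, constrained and linear-EC estimators."""

    reference: str
    target_decade: str
    default_rmse: float
    default_r2: float
    constrained_rmse: float
    constrained_r2: float
    linear_ec_rmse: float
    linear_ec_r2: float
    per_source: dict
    training_log: list
    seed: int

    def as_dict(self) -> dict:
        return {
            "reference": self.reference,
            "target_decade": self.target_decade,
            "default_rmse": self.default_rmse,
            "default_r2": self.default_r2,
            "constrained_rmse": self.constrained_rmse,
            "constrained_r2": self.constrained_r2,
            "linear_ec_rmse": self.linear_ec_rmse,
            "linear_ec_r2": self.linear_ec_r2,
            "per_source": self.per_source,
            "seed": self.seed,
        }


def holdout_validation(
    world: SyntheticWorld,
    algorithms: Sequence[str] = ALGORITHMS,
    combination_cap: int = 8,
    mlt_overrides: Mapping | None = None,
    seed: int = 0,
    training_spec: GridSpec | None = None,
    ensemble: "object | None" = None,
    sources: Sequence | None = None,
) -> ValidationReport:
    """Train on (first decade -> second decade), score against the truth.

    Mirrors validating the constraint on a held-out historical decade: the
    learners never see the reference (truth) emission of the target decade.
    A precomputed ``ensemble`` for the target decade may be passed to avoid
    retraining.
    """
    from .constrain import run_constraint

    cfg = world.config
    target_decade = cfg.decades[1]
    truth = world.truth_emission[target_decade]

    if ensemble is None:
        ensemble = run_constraint(
            world,
            decades=[target_decade],
            algorithms=algorithms,
            sources=sources,
            combination_cap=combination_cap,
            mlt_overrides=mlt_overrides,
            seed=seed,
            training_spec=training_spec,
        )
    constrained_mean = ensemble.mean_field(target_decade)

    member_future = [world.member_emission[i][target_decade] for i in range(cfg.n_models)]
    default_mean = member_future[0].copy_with(
        values=np.mean([f.values for f in member_future], axis=0)
    )

    member_hist = [world.member_emission[i][world.hist_decade] for i in range(cfg.n_models)]
    obs_emission = world.observations["fire_carbon_emission"][0]["annual"]
    ec_field = gridwise_linear_ec(member_hist, member_future, obs_emission)

    def _safe_r2(a: Field, b: Field) -> float:
        try:
            return spatial_r2(a, b)
        except ValueError:  # constant member field (e.g. an all-zero simulation)
            return float("nan")

    per_source: dict = {}
    for i in range(cfg.n_models):
        own = [
            f
            for (s, c, a, d), f in ensemble.members.items()
            if s == str(i) and d == target_decade
        ]
        entry = {
            "default_rmse": rmse(member_future[i], truth),
            "default_r2": _safe_r2(member_future[i], truth),
        }
        if own:
            agg = np.mean([f.values for f in own], axis=0)
            mean_i = truth.copy_with(values=agg)
            entry["constrained_rmse"] = rmse(mean_i, truth)
            entry["constrained_r2"] = _safe_r2(mean_i, truth)
        per_source[str(i)] = entry

    return ValidationReport(
        reference="synthetic_truth",
        target_decade=target_decade,
        default_rmse=rmse(default_mean, truth),
        default_r2=spatial_r2(default_mean, truth),
        constrained_rmse=rmse(constrained_mean, truth),
        constrained_r2=spatial_r2(constrained_mean, truth),
        linear_ec_rmse=rmse(ec_field, truth),
        linear_ec_r2=spatial_r2(ec_field, truth),
        per_source=per_source,
        training_log=ensemble.training_log,
        seed=seed,
    )


def resolution_sweep(
    world: SyntheticWorld,
    resolutions: Sequence[float],
    algorithms: Sequence[str] = ALGORITHMS,
    combination_cap: int = 4,
    mlt_overrides: Mapping | None = None,
    seed: int = 0,
) -> dict[float, ValidationReport]:
    """Hold-out validation with training fields coarsened to each resolution.

    Observations are fed at their native resolution regardless of the
    training grid, so only the training-sample resolution varies.
    """
    out = {}
    for res in resolutions:
        spec = None if res == world.spec.resolution else GridSpec.global_grid(res)
        out[res] = holdout_validation(
            world,
            algorithms=algorithms,
            combination_cap=combination_cap,
            mlt_overrides=mlt_overrides,
            seed=child_seed(seed, "res", res),
            training_spec=spec,
        )
    return out
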