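"""Traditional emergent-constraint baseline.

An emergent constraint is an across-model ordinary least squares relationship
between a measurable historical quantity x and an unobservable future
quantity y; evaluating the line at the observed x, with Gaussian uncertainty
propagation, yields the constrained estimate.  Applied here both to scalars
(e.g. global totals across ensemble members) and per grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import GridwiseLinearEC
from .grid import Field

__all__ = ["EmergentLine", "fit_line", "constrain_scalar", "gridwise_linear_ec"]


@dataclass(frozen=True)
class EmergentLine:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_models: int
    residual_sd: float
    x_mean: float
    sxx: float


def fit_line(x: np.ndarray, y: np.ndarray) -> EmergentLine:
    """Across-model OLS line with a two-sided p-value for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 ensemble members")
    if np.var(x) == 0:
        raise ValueError("degenerate constraint: historical quantity has zero variance")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    s = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return EmergentLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_models=n,
        residual_sd=s,
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def constrain_scalar(line: EmergentLine, x_obs: float, sigma_obs: float = 0.0) -> dict:
    """Constrained estimate at the observed value.

    The spread combines the OLS prediction standard error at x_obs with the
    observational uncertainty mapped through the slope, in quadrature.
    """
    mean = line.intercept + line.slope * x_obs
    if line.sxx > 0:
        pred_var = line.residual_sd**2 * (
            1.0 + 1.0 / line.n_models + (x_obs - line.x_mean) ** 2 / line.sxx
        )
    else:
        pred_var = line.residual_sd**2
    sd = float(np.sqrt(pred_var + (line.slope * sigma_obs) ** 2))
    return {"mean": float(mean), "sd": sd}


def gridwise_linear_ec(
    members_hist: Sequence[Field],
    members_future: Sequence[Field],
    obs_hist: Field,
    p_threshold: float | None = None,
) -> Field:
    """Per-cell emergent constraint of a future field by an observed one.

    Degenerate (or, with ``p_threshold``, insignificant) cells fall back to
    the unconstrained multimodel-mean future value.
    """
    spec = obs_hist.spec
    for f in list(members_hist) + list(members_future):
        if f.spec != spec:
            raise ValueError("all fields must share the observation grid")
    if len(members_hist) != len(members_future):
        raise ValueError("historical and future member counts differ")
    X = np.stack([f.values.ravel() for f in members_hist])
    Y = np.stack([f.values.ravel() for f in members_future])
    model = GridwiseLinearEC(p_threshold=p_threshold).fit(X, Y)
    pred = model.predict(obs_hist.values.ravel()).reshape(spec.shape)
    pred = np.clip(pred, 0.0, None)
    return Field(
        spec,
        np.where(obs_hist.mask, pred, 0.0),
        obs_hist.mask,
        members_future[0].variable_id,
        members_future[0].units,
        members_future[0].time_tag,
    )
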