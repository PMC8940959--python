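"""Socioeconomic exposure to fire carbon emission.

Exposure is the per-cell product of decadal-mean fire carbon emission (a flux
density, kg m-2 yr-1) and the amount of population, GDP or agricultural area
in the cell, so its totals are plain sums over cells, not area integrals.
Relative trends (% per decade) divide the OLS decadal trend by the
second-decade (2010s) value; regions with zero baseline exposure are
excluded from rankings rather than reported as infinite trends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import decadal_trend
from .grid import Field, RegionMap, field_sum, region_totals

__all__ = ["ExposureSeries", "exposure_field", "exposure_series", "rank_countries"]


@dataclass
class ExposureSeries:
    metric: str
    decades: tuple
    fields: dict  # decade -> Field
    global_totals: pd.Series
    region_totals: pd.DataFrame  # index region id, columns decades
    global_relative_trend: float
    region_relative_trends: pd.Series
    region_names: Mapping[int, str]


def exposure_field(emission: Field, socio: Field) -> Field:
    """Per-cell product of emission flux density and a socio amount."""
    if emission.spec != socio.spec:
        raise ValueError("emission and socio fields are on different grids")
    mask = emission.mask & socio.mask
    values = np.where(mask, emission.values * socio.values, 0.0)
    return Field(
        emission.spec,
        values,
        mask,
        f"exposure_{socio.variable_id}",
        f"{emission.units} {socio.units}",
        emission.time_tag,
    )


def exposure_series(
    emissions: Mapping[str, Field],
    socio: Mapping[str, Field],
    regions: RegionMap,
    metric: str,
    baseline_index: int = 1,
) -> ExposureSeries:
    """Decadal exposure fields with global/national totals and relative trends."""
    decades = tuple(emissions)
    if tuple(socio) != decades:
        raise ValueError("emission and socio decade sets differ")
    fields = {d: exposure_field(emissions[d], socio[d]) for d in decades}
    g = pd.Series({d: field_sum(fields[d]) for d in decades}, name=f"exposure_{metric}")
    reg = pd.DataFrame(
        {d: region_totals(fields[d], regions, per_area=False) for d in decades}
    )
    g_trend = decadal_trend(g.to_numpy(), baseline_index=baseline_index)["relative_pct"]
    rel = {}
    for rid in reg.index:
        series = reg.loc[rid].to_numpy()
        if series[baseline_index] == 0:
            rel[rid] = np.nan
        else:
            rel[rid] = decadal_trend(series, baseline_index=baseline_index)["relative_pct"]
    return ExposureSeries(
        metric=metric,
        decades=decades,
        fields=fields,
        global_totals=g,
        region_totals=reg,
        global_relative_trend=float(g_trend),
        region_relative_trends=pd.Series(rel),
        region_names=dict(regions.names),
    )


def rank_countries(series: ExposureSeries, n: int = 10) -> list[int]:
    """Region ids with the greatest relative exposure trends, descending.

    Ties break toward the lower region id; regions with undefined (zero
    baseline) trends are excluded.
    """
    trends = series.region_relative_trends.dropna()
    order = sorted(trends.index, key=lambda rid: (-trends[rid], rid))
    return [int(r) for r in order[:n]]
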