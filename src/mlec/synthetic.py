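"""Synthetic pseudo-model ensembles with a known driver -> fire link.

The generator emulates the structure of a multimodel fire-emission ensemble:
a "truth" world with smooth driver fields (fuel, moisture, spread and
ignition variables), a fixed nonlinear link g mapping drivers to fire carbon
emission, an ensemble of pseudo-models that see biased drivers through
perturbed copies of g (so each member has an internally consistent
history-future relationship), noisy observational datasets of the historical
truth, and gridded socioeconomic projections with prescribed per-region
growth.  Every quantity is reproducible bit-for-bit from the config seed.

The link g multiplies a saturating fuel term (LAI, precipitation,
temperature), a logistic dryness term (soil moisture, relative humidity), a
humped ignition term (flash rate, population, land use) and a wind spread
factor; it is deliberately nonlinear and interactive so that a per-gridcell
linear constraint is beatable.  A purely linear link is available for
baseline-equivalence experiments (``link="linear"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dfield
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ._rng import rng
from .grid import Field, GridSpec, RegionMap

__all__ = [
    "DYNAMIC_VARIABLES",
    "STATIC_VARIABLES",
    "PREDICTOR_VARIABLES",
    "SOCIO_METRICS",
    "WorldConfig",
    "SyntheticWorld",
    "generate_truth",
    "generate_models",
    "generate_socio",
    "generate_world",
    "evaluate_link",
]

# variables with annual mean + 12-month climatology encodings
DYNAMIC_VARIABLES = (
    "fire_carbon_emission",
    "lai",
    "precipitation",
    "rel_humidity",
    "soil_moisture",
    "temperature",
    "wind",
)
# single-encoding variables (terrain, lightning climatology, decadal socio products)
STATIC_VARIABLES = ("flash_rate", "land_use", "orography", "population")
PREDICTOR_VARIABLES = DYNAMIC_VARIABLES + STATIC_VARIABLES

SOCIO_METRICS = ("population", "gdp", "agricultural_area")

_UNITS = {
    "fire_carbon_emission": "kg m-2 yr-1",
    "lai": "m2 m-2",
    "precipitation": "mm day-1",
    "rel_humidity": "%",
    "soil_moisture": "m3 m-3",
    "temperature": "K",
    "wind": "m s-1",
    "flash_rate": "km-2 yr-1 flashes",
    "land_use": "crop fraction",
    "orography": "m",
    "population": "person",
    "gdp": "billion USD",
    "agricultural_area": "km2",
}

# environmental drivers that receive per-model additive bias fields
_BIASED_DRIVERS = ("lai", "precipitation", "rel_humidity", "soil_moisture", "temperature", "wind")

_DEFAULT_DECADES = tuple(f"{y}s" for y in range(2000, 2100, 10))

# per-decade drift, in units of each driver's historical spatial sd
_DEFAULT_TRENDS = {
    "temperature": 0.25,
    "soil_moisture": -0.15,
    "rel_humidity": -0.10,
    "precipitation": 0.05,
    "lai": 0.10,
    "wind": 0.0,
    "land_use": 0.05,
}

_DEFAULT_LINK_PARAMS = {
    "e0": 0.6,
    "lai_half": 1.5,
    "pr_half": 2.0,
    "t0": 284.0,
    "t_scale": 6.0,
    "sm0": 0.22,
    "sm_scale": 0.05,
    "rh0": 55.0,
    "rh_scale": 12.0,
    "flash0": 10.0,
    "flash_scale": 6.0,
    "ign_base": 0.3,
    "pop0": 8e4,
    "lu_suppress": 0.5,
    "wind0": 5.0,
    "wind_scale": 2.0,
}

# linear-link weights on standardized drivers, kg m-2 yr-1 per sd
_LINEAR_CENTERS = {
    "lai": (2.5, 1.5),
    "precipitation": (3.0, 2.5),
    "rel_humidity": (60.0, 15.0),
    "soil_moisture": (0.2, 0.08),
    "temperature": (285.0, 15.0),
    "wind": (5.0, 2.0),
    "flash_rate": (12.0, 8.0),
    "land_use": (0.3, 0.2),
    "population": (8e4, 1.2e5),
}
_DEFAULT_LINEAR_PARAMS = {
    "c0": 0.05,
    "w_lai": 0.010,
    "w_precipitation": 0.004,
    "w_rel_humidity": -0.010,
    "w_soil_moisture": -0.012,
    "w_temperature": 0.012,
    "w_wind": 0.003,
    "w_flash_rate": 0.004,
    "w_land_use": -0.003,
    "w_population": 0.003,
}


@dataclass
class WorldConfig:
    """Study conditions of the synthetic world."""

    spec: GridSpec = _dfield(default_factory=lambda: GridSpec.global_grid(5.0))
    n_models: int = 8
    n_obs_datasets: int = 2
    decades: Sequence[str] = _DEFAULT_DECADES
    seed: int = 0
    model_bias_amplitude: float = 1.5
    link_perturbation: float = 0.3
    trend_spread: float = 0.5
    obs_noise_sd: float = 0.1
    link: str = "nonlinear"  # or "linear"
    planted_driver: str | None = None  # emission responds to this driver only
    driver_trends: Mapping[str, float] = _dfield(default_factory=lambda: dict(_DEFAULT_TRENDS))
    seasonal_amplitude: float = 0.3
    land_fraction: float = 0.35
    n_regions: int = 12
    socio_growth_ranges: Mapping[str, tuple[float, float]] = _dfield(
        default_factory=lambda: {
            "population": (0.00, 0.12),
            "gdp": (0.08, 0.35),
            "agricultural_area": (0.00, 0.06),
        }
    )
    socio_growth_override: Mapping[str, Mapping[int, float]] = _dfield(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need at least 2 pseudo-models")
        if len(self.decades) < 2:
            raise ValueError("need at least 2 decades")
        for name, amp in (
            ("model_bias_amplitude", self.model_bias_amplitude),
            ("link_perturbation", self.link_perturbation),
            ("obs_noise_sd", self.obs_noise_sd),
        ):
            if amp < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.link not in ("nonlinear", "linear"):
            raise ValueError("link must be 'nonlinear' or 'linear'")

    @property
    def hist_decade(self) -> str:
        return self.decades[0]


@dataclass
class SyntheticWorld:
    config: WorldConfig
    land_mask: np.ndarray
    regions: RegionMap
    # var -> decade -> annual-mean Field (env drivers + land_use)
    truth_drivers: dict
    # var -> 12 calendar-month climatology Fields for the historical decade
    truth_monthly: dict
    truth_statics: dict  # flash_rate, orography
    truth_emission: dict  # decade -> Field
    truth_emission_monthly: list
    link_params: dict
    member_drivers: list
    member_monthly: list
    member_emission: list
    member_link_params: list
    # var -> [dataset k -> {"annual": Field, "monthly": list[Field] | None}]
    observations: dict
    socio: dict  # metric -> decade -> Field
    socio_growth: dict  # metric -> region id -> growth per decade

    # ------------------------------------------------------------------
    @property
    def spec(self) -> GridSpec:
        return self.config.spec

    @property
    def hist_decade(self) -> str:
        return self.config.hist_decade

    def predictor_fields(self, source, decade: str | None = None) -> dict:
        """Predictor fields (annual + monthly climatology) for one source.

        ``source`` is a member index, ``"truth"``, or ``"multimodel_mean"``;
        ``decade`` defaults to the historical decade.  Monthly climatologies
        are only available for the historical decade.
        """
        decade = decade or self.hist_decade
        monthly_ok = decade == self.hist_decade
        if source == "multimodel_mean":
            per_member = [self.predictor_fields(i, decade) for i in range(self.config.n_models)]
            return _average_predictor_sets(per_member)
        if source == "truth":
            drivers, monthly, emission = self.truth_drivers, self.truth_monthly, self.truth_emission
            emission_monthly = self.truth_emission_monthly
        else:
            i = int(source)
            drivers, monthly = self.member_drivers[i], self.member_monthly[i]
            emission, emission_monthly = self.member_emission[i], None
            emission_monthly = self.member_monthly[i].get("fire_carbon_emission")
        out: dict = {}
        for var in DYNAMIC_VARIABLES:
            if var == "fire_carbon_emission":
                annual = emission[decade]
                months = emission_monthly if monthly_ok else None
            else:
                annual = drivers[var][decade]
                months = monthly.get(var) if monthly_ok else None
            out[var] = {"annual": annual, "monthly": months}
        for var in ("flash_rate", "orography"):
            out[var] = {"annual": self.truth_statics[var], "monthly": None}
        out["land_use"] = {"annual": self.truth_drivers["land_use"][decade], "monthly": None}
        out["population"] = {"annual": self.socio["population"][decade], "monthly": None}
        return out

    def target_emission(self, source, decade: str) -> Field:
        if source == "truth":
            return self.truth_emission[decade]
        if source == "multimodel_mean":
            stack = np.mean([self.member_emission[i][decade].values for i in range(self.config.n_models)], axis=0)
            ref = self.member_emission[0][decade]
            return ref.copy_with(values=stack)
        return self.member_emission[int(source)][decade]


def _average_predictor_sets(sets: list[dict]) -> dict:
    out: dict = {}
    for var, entry in sets[0].items():
        annual = entry["annual"].copy_with(
            values=np.mean([s[var]["annual"].values for s in sets], axis=0)
        )
        months = None
        if entry["monthly"] is not None:
            months = [
                entry["monthly"][m].copy_with(
                    values=np.mean([s[var]["monthly"][m].values for s in sets], axis=0)
                )
                for m in range(12)
            ]
        out[var] = {"annual": annual, "monthly": months}
    return out


# ---------------------------------------------------------------------------
# field-level helpers


def _smooth_noise(r: np.random.Generator, spec: GridSpec, sigma: float = 2.0) -> np.ndarray:
    """Zero-mean, unit-sd smooth random field (periodic in longitude)."""
    raw = r.standard_normal(spec.shape)
    sm = gaussian_filter(raw, sigma=sigma, mode=("nearest", "wrap"))
    sm -= sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def evaluate_link(
    drivers: Mapping[str, np.ndarray],
    params: Mapping[str, float],
    link: str = "nonlinear",
    planted_driver: str | None = None,
) -> np.ndarray:
    """The driver -> fire carbon emission link g (kg m-2 yr-1)."""
    if planted_driver is not None:
        # single-driver world: a logistic response to one variable only,
        # decreasing for the moisture variables, increasing otherwise
        center, scale = _LINEAR_CENTERS.get(planted_driver, (0.0, 1.0))
        sign = -1.0 if planted_driver in ("soil_moisture", "rel_humidity") else 1.0
        z = sign * (drivers[planted_driver] - center) / scale
        return 0.05 * _logistic(1.5 * z)
    if link == "linear":
        z = params["c0"] * np.ones_like(drivers["temperature"])
        for var, (center, scale) in _LINEAR_CENTERS.items():
            z = z + params[f"w_{var}"] * (drivers[var] - center) / scale
        return np.clip(z, 0.0, None)
    p = params
    lai, pr, t = drivers["lai"], drivers["precipitation"], drivers["temperature"]
    sm, rh = drivers["soil_moisture"], drivers["rel_humidity"]
    fuel = (lai / (lai + p["lai_half"])) * (pr / (pr + p["pr_half"])) * _logistic((t - p["t0"]) / p["t_scale"])
    dryness = _logistic((p["sm0"] - sm) / p["sm_scale"]) * _logistic((p["rh0"] - rh) / p["rh_scale"])
    flash_term = p["ign_base"] + (1 - p["ign_base"]) * _logistic(
        (drivers["flash_rate"] - p["flash0"]) / p["flash_scale"]
    )
    pop_ratio = drivers["population"] / p["pop0"]
    humped = 2.0 * pop_ratio / (1.0 + pop_ratio**2)
    ignition = flash_term * humped * (1.0 - p["lu_suppress"] * drivers["land_use"])
    spread = 0.5 + 0.5 * _logistic((drivers["wind"] - p["wind0"]) / p["wind_scale"])
    return np.clip(p["e0"] * fuel * dryness * ignition * spread, 0.0, None)


_RANGES = {
    "lai": (0.0, 7.0),
    "precipitation": (0.05, 25.0),
    "rel_humidity": (3.0, 99.0),
    "soil_moisture": (0.01, 0.48),
    "temperature": (230.0, 320.0),
    "wind": (0.2, 20.0),
    "land_use": (0.0, 0.95),
}


def _base_drivers(cfg: WorldConfig) -> dict[str, np.ndarray]:
    """Historical-decade truth driver patterns (latitudinal structure + smooth noise).

    In planted-driver mode the drivers are generated mutually independent:
    the physically motivated couplings (soil moisture from precipitation,
    LAI from climate) would make the planted signal non-identifiable —
    importance would legitimately split between collinear variables.
    """
    spec = cfg.spec
    lat = np.deg2rad(spec.lat_centers)[:, None] * np.ones((1, spec.n_lon))
    lat_deg = np.rad2deg(lat)

    def noise(tag: str, sigma: float = 2.0) -> np.ndarray:
        return _smooth_noise(rng(cfg.seed, "truth", tag), spec, sigma)

    if cfg.planted_driver is not None:
        return {
            "temperature": np.clip(285.0 + 12.0 * noise("temperature"), *_RANGES["temperature"]),
            "precipitation": np.clip(4.0 + 2.2 * noise("precipitation"), *_RANGES["precipitation"]),
            "rel_humidity": np.clip(55.0 + 15.0 * noise("rel_humidity"), *_RANGES["rel_humidity"]),
            "soil_moisture": np.clip(0.20 + 0.07 * noise("soil_moisture"), *_RANGES["soil_moisture"]),
            "lai": np.clip(3.0 + 1.3 * noise("lai"), *_RANGES["lai"]),
            "wind": np.clip(5.0 + 2.0 * noise("wind"), *_RANGES["wind"]),
            "land_use": np.clip(0.3 + 0.15 * noise("land_use"), *_RANGES["land_use"]),
        }

    t = 302.0 - 50.0 * np.sin(lat) ** 2 + 4.0 * noise("temperature")
    pr = np.clip(
        9.0 * np.exp(-((lat_deg / 20.0) ** 2))
        + 2.5 * np.exp(-(((np.abs(lat_deg) - 45.0) / 12.0) ** 2))
        + 1.8 * noise("precipitation"),
        *_RANGES["precipitation"],
    )
    rh = np.clip(50.0 + 22.0 * np.exp(-((lat_deg / 18.0) ** 2)) + 10.0 * noise("rel_humidity"), *_RANGES["rel_humidity"])
    sm = np.clip(0.10 + 0.020 * pr + 0.035 * noise("soil_moisture"), *_RANGES["soil_moisture"])
    lai = np.clip(
        6.5 * (pr / (pr + 3.0)) * _logistic((t - 278.0) / 6.0) + 0.5 * noise("lai"),
        *_RANGES["lai"],
    )
    wind = np.clip(5.0 + 2.0 * noise("wind"), *_RANGES["wind"])
    lu = np.clip(0.25 + 0.2 * noise("land_use"), *_RANGES["land_use"])
    return {
        "temperature": t,
        "precipitation": pr,
        "rel_humidity": rh,
        "soil_moisture": sm,
        "lai": lai,
        "wind": wind,
        "land_use": lu,
    }


def _make_regions(cfg: WorldConfig, land: np.ndarray) -> RegionMap:
    """Synthetic countries: contiguous lat/lon blocks intersected with land."""
    spec = cfg.spec
    n = cfg.n_regions
    n_rows = max(1, int(round(np.sqrt(n / 2))))
    n_cols = int(np.ceil(n / n_rows))
    row = np.minimum((np.arange(spec.n_lat) * n_rows) // spec.n_lat, n_rows - 1)
    col = np.minimum((np.arange(spec.n_lon) * n_cols) // spec.n_lon, n_cols - 1)
    block = row[:, None] * n_cols + col[None, :]
    region_id = np.where(land, np.minimum(block, n - 1) + 1, 0)
    names = {i + 1: f"country_{i + 1:02d}" for i in range(n)}
    present = set(np.unique(region_id)) - {0}
    names = {i: names[i] for i in sorted(present)}
    return RegionMap(spec, region_id, names)


def _seasonal_cycle(cfg: WorldConfig, var: str, annual: np.ndarray, land: np.ndarray) -> list[np.ndarray]:
    """12 calendar-month values: annual mean + hemisphere-phased harmonic."""
    spec = cfg.spec
    lat = spec.lat_centers[:, None] * np.ones((1, spec.n_lon))
    r = rng(cfg.seed, "seasonal", var)
    phase = r.uniform(-1.0, 1.0)
    sd = annual[land].std() if land.any() else annual.std()
    amp = cfg.seasonal_amplitude * sd * np.sin(np.deg2rad(lat))
    months = []
    for m in range(12):
        harm = np.cos(2.0 * np.pi * (m - 6.0 + phase) / 12.0)
        vals = annual + amp * harm
        if var in _RANGES:
            vals = np.clip(vals, *_RANGES[var])
        elif var == "fire_carbon_emission":
            vals = np.clip(vals, 0.0, None)
        months.append(vals)
    # recentre so the climatological mean equals the annual mean exactly
    mean = np.mean(months, axis=0)
    months = [m_ + (annual - mean) for m_ in months]
    if var == "fire_carbon_emission":
        months = [np.clip(m_, 0.0, None) for m_ in months]
    return months


def _field(cfg: WorldConfig, values: np.ndarray, mask: np.ndarray, var: str, tag: str) -> Field:
    return Field(cfg.spec, values, mask, var, _UNITS[var], tag)


def _trend_patterns(cfg: WorldConfig) -> dict[str, np.ndarray]:
    out = {}
    for var in _DEFAULT_TRENDS:
        pat = 1.0 + 0.5 * _smooth_noise(rng(cfg.seed, "trendpat", var), cfg.spec)
        out[var] = np.clip(pat, 0.0, None)
    return out


# ---------------------------------------------------------------------------
# generators


def generate_truth(cfg: WorldConfig) -> SyntheticWorld:
    """Truth drivers, emission, observations, land mask and regions."""
    spec = cfg.spec
    land_score = _smooth_noise(rng(cfg.seed, "land"), spec, sigma=2.5)
    thresh = np.quantile(land_score, 1.0 - cfg.land_fraction)
    land = (land_score > thresh) & (np.abs(spec.lat_centers)[:, None] < 84.0)
    regions = _make_regions(cfg, land)

    base = _base_drivers(cfg)
    statics_vals = {
        "flash_rate": np.clip(
            25.0 * np.exp(-((spec.lat_centers[:, None] / 25.0) ** 2)) * np.ones((1, spec.n_lon))
            + 8.0 * _smooth_noise(rng(cfg.seed, "truth", "flash_rate"), spec),
            0.0,
            None,
        ),
        "orography": np.clip(800.0 + 900.0 * _smooth_noise(rng(cfg.seed, "truth", "orography"), spec), 0.0, None),
    }
    statics = {v: _field(cfg, vals, land, v, "static") for v, vals in statics_vals.items()}

    socio, socio_growth = _socio_fields(cfg, land, regions)

    patterns = _trend_patterns(cfg)
    sds = {v: base[v][land].std() for v in base}
    link_params = dict(_DEFAULT_LINK_PARAMS if cfg.link == "nonlinear" else _DEFAULT_LINEAR_PARAMS)

    truth_drivers: dict = {v: {} for v in base}
    truth_emission: dict = {}
    for d, decade in enumerate(cfg.decades):
        decade_vals = {}
        for var, vals in base.items():
            drift = cfg.driver_trends.get(var, 0.0) * sds[var] * d * patterns.get(var, 1.0)
            shifted = np.clip(vals + drift, *_RANGES[var])
            decade_vals[var] = shifted
            truth_drivers[var][decade] = _field(cfg, shifted, land, var, decade)
        all_drivers = {
            **decade_vals,
            **statics_vals,
            "population": socio["population"][decade].values,
        }
        emission = evaluate_link(all_drivers, link_params, cfg.link, cfg.planted_driver)
        truth_emission[decade] = _field(cfg, emission, land, "fire_carbon_emission", decade)

    hist = cfg.hist_decade
    truth_monthly = {
        var: [
            _field(cfg, vals, land, var, f"{hist}-m{m + 1:02d}")
            for m, vals in enumerate(_seasonal_cycle(cfg, var, truth_drivers[var][hist].values, land))
        ]
        for var in base
        if var != "land_use"
    }
    emission_monthly = [
        _field(cfg, vals, land, "fire_carbon_emission", f"{hist}-m{m + 1:02d}")
        for m, vals in enumerate(
            _seasonal_cycle(cfg, "fire_carbon_emission", truth_emission[hist].values, land)
        )
    ]

    observations = _observations(cfg, land, truth_drivers, truth_monthly, truth_emission, emission_monthly, statics, socio)

    return SyntheticWorld(
        config=cfg,
        land_mask=land,
        regions=regions,
        truth_drivers=truth_drivers,
        truth_monthly=truth_monthly,
        truth_statics=statics,
        truth_emission=truth_emission,
        truth_emission_monthly=emission_monthly,
        link_params=link_params,
        member_drivers=[],
        member_monthly=[],
        member_emission=[],
        member_link_params=[],
        observations=observations,
        socio=socio,
        socio_growth=socio_growth,
    )


def _observations(cfg, land, truth_drivers, truth_monthly, truth_emission, emission_monthly, statics, socio):
    """Noisy copies of the historical truth, one list of datasets per variable."""
    hist = cfg.hist_decade
    obs: dict = {}
    for var in PREDICTOR_VARIABLES:
        datasets = []
        for k in range(cfg.n_obs_datasets):
            if var == "fire_carbon_emission":
                annual_truth = truth_emission[hist].values
                months_truth = [f.values for f in emission_monthly]
            elif var in ("flash_rate", "orography"):
                annual_truth = statics[var].values
                months_truth = None
            elif var == "population":
                annual_truth = socio["population"][hist].values
                months_truth = None
            elif var == "land_use":
                annual_truth = truth_drivers["land_use"][hist].values
                months_truth = None
            else:
                annual_truth = truth_drivers[var][hist].values
                months_truth = [f.values for f in truth_monthly[var]]
            sd = annual_truth[land].std()
            noise = cfg.obs_noise_sd * sd * _smooth_noise(rng(cfg.seed, "obs", var, k), cfg.spec)
            annual = annual_truth + noise
            if var in _RANGES:
                annual = np.clip(annual, *_RANGES[var])
            elif var in ("fire_carbon_emission", "flash_rate", "orography", "population"):
                annual = np.clip(annual, 0.0, None)
            entry = {
                "annual": _field(cfg, annual, land, var, hist),
                "monthly": None,
            }
            if months_truth is not None:
                months = []
                for m, mv in enumerate(months_truth):
                    v = mv + noise  # decade-scale dataset bias shared across months
                    if var in _RANGES:
                        v = np.clip(v, *_RANGES[var])
                    elif var == "fire_carbon_emission":
                        v = np.clip(v, 0.0, None)
                    months.append(_field(cfg, v, land, var, f"{hist}-m{m + 1:02d}"))
                entry["monthly"] = months
            datasets.append(entry)
        obs[var] = datasets
    return obs


# location parameters shift additively on their paired scale; everything else
# (amplitudes, half-saturation constants, widths) perturbs multiplicatively
_LOCATION_PARAMS = {
    "t0": "t_scale",
    "sm0": "sm_scale",
    "rh0": "rh_scale",
    "flash0": "flash_scale",
    "wind0": "wind_scale",
}


def _perturb_link(params: dict, link: str, amplitude: float, r: np.random.Generator) -> dict:
    out = {}
    for k, v in params.items():
        if link == "nonlinear" and k in _LOCATION_PARAMS:
            out[k] = v + amplitude * params[_LOCATION_PARAMS[k]] * r.standard_normal()
        else:
            out[k] = v * (1.0 + amplitude * r.standard_normal())
    return out


def generate_models(cfg: WorldConfig, world: SyntheticWorld) -> SyntheticWorld:
    """Pseudo-models: biased drivers + perturbed link, self-consistent in time."""
    land = world.land_mask
    hist = cfg.hist_decade
    base_decade = cfg.decades[0]
    for i in range(cfg.n_models):
        biases = {}
        for var in _BIASED_DRIVERS:
            sd = world.truth_drivers[var][hist].values[land].std()
            biases[var] = (
                cfg.model_bias_amplitude * sd * _smooth_noise(rng(cfg.seed, "bias", i, var), cfg.spec)
            )
        # models disagree about projected driver changes: each member scales
        # the truth's decadal drift by its own factor (mean 1 across members)
        rt = rng(cfg.seed, "trend", i)
        trend_scale = {
            var: 1.0 + cfg.trend_spread * rt.standard_normal() for var in sorted(_BIASED_DRIVERS)
        }
        r = rng(cfg.seed, "link", i)
        params = _perturb_link(world.link_params, cfg.link, cfg.link_perturbation, r)
        drivers: dict = {v: {} for v in world.truth_drivers}
        emission: dict = {}
        for decade in cfg.decades:
            decade_vals = {}
            for var in world.truth_drivers:
                vals = world.truth_drivers[var][decade].values
                if var in biases:
                    drift = vals - world.truth_drivers[var][base_decade].values
                    vals = np.clip(
                        world.truth_drivers[var][base_decade].values
                        + trend_scale[var] * drift
                        + biases[var],
                        *_RANGES[var],
                    )
                decade_vals[var] = vals
                drivers[var][decade] = _field(cfg, vals, land, var, decade)
            all_drivers = {
                **decade_vals,
                "flash_rate": world.truth_statics["flash_rate"].values,
                "orography": world.truth_statics["orography"].values,
                "population": world.socio["population"][decade].values,
            }
            emission[decade] = _field(
                cfg,
                evaluate_link(all_drivers, params, cfg.link, cfg.planted_driver),
                land,
                "fire_carbon_emission",
                decade,
            )
        monthly: dict = {}
        for var, months in world.truth_monthly.items():
            b = biases.get(var, 0.0)
            vals = []
            for m, f in enumerate(months):
                v = f.values + b
                if var in _RANGES:
                    v = np.clip(v, *_RANGES[var])
                vals.append(_field(cfg, v, land, var, f.time_tag))
            monthly[var] = vals
        # member fire seasonality: truth seasonal shape rescaled to the member annual mean
        truth_ann = world.truth_emission[hist].values
        scale = np.where(truth_ann > 1e-12, emission[hist].values / np.clip(truth_ann, 1e-12, None), 1.0)
        monthly["fire_carbon_emission"] = [
            _field(cfg, np.clip(f.values * scale, 0.0, None), land, "fire_carbon_emission", f.time_tag)
            for f in world.truth_emission_monthly
        ]
        world.member_drivers.append(drivers)
        world.member_monthly.append(monthly)
        world.member_emission.append(emission)
        world.member_link_params.append(params)
    return world


def _socio_fields(cfg: WorldConfig, land: np.ndarray, regions: RegionMap):
    """Socio projections with prescribed geometric per-region growth."""
    spec = cfg.spec
    lat = spec.lat_centers[:, None] * np.ones((1, spec.n_lon))
    base = {
        "population": 2e5
        * np.exp(1.5 * _smooth_noise(rng(cfg.seed, "socio", "population"), spec))
        * np.exp(-(((lat + 10.0) / 50.0) ** 2)),
        "gdp": 0.5 * np.exp(1.2 * _smooth_noise(rng(cfg.seed, "socio", "gdp"), spec)),
        "agricultural_area": np.clip(
            600.0 + 500.0 * _smooth_noise(rng(cfg.seed, "socio", "agricultural_area"), spec), 0.0, None
        ),
    }
    growth: dict = {}
    fields: dict = {m: {} for m in SOCIO_METRICS}
    for metric in SOCIO_METRICS:
        lo, hi = cfg.socio_growth_ranges[metric]
        r = rng(cfg.seed, "socio-growth", metric)
        rates = {rid: float(r.uniform(lo, hi)) for rid in regions.ids}
        rates.update(cfg.socio_growth_override.get(metric, {}))
        growth[metric] = rates
        rate_map = np.zeros(spec.shape)
        for rid, rate in rates.items():
            rate_map[regions.region_id == rid] = rate
        vals = np.where(land, base[metric], 0.0)
        for d, decade in enumerate(cfg.decades):
            fields[metric][decade] = _field(cfg, vals * (1.0 + rate_map) ** d, land, metric, decade)
    return fields, growth


def generate_socio(cfg: WorldConfig, land: np.ndarray | None = None, regions: RegionMap | None = None):
    """Standalone socio generator (land/regions regenerated from the seed if omitted)."""
    if land is None or regions is None:
        spec = cfg.spec
        score = _smooth_noise(rng(cfg.seed, "land"), spec, sigma=2.5)
        thresh = np.quantile(score, 1.0 - cfg.land_fraction)
        land = (score > thresh) & (np.abs(spec.lat_centers)[:, None] < 84.0)
        regions = _make_regions(cfg, land)
    return _socio_fields(cfg, land, regions)


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Full world: truth + observations + pseudo-model ensemble + socio."""
    return generate_models(cfg, generate_truth(cfg))


def save_world(world: SyntheticWorld, out_dir) -> None:
    """Write a world as a directory of NetCDF files plus a JSON manifest.

    Truth emission and drivers (annual means per decade), member emissions,
    observation annuals, socio fields and the region map are written; the
    manifest records the generating config and seed, from which the full
    world (including monthly climatologies) is reproducible.
    """
    import json
    from pathlib import Path

    from .grid import save_field, save_region_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    for decade in cfg.decades:
        save_field(world.truth_emission[decade], out / f"truth_fire_carbon_emission_{decade}.nc")
        for var in world.truth_drivers:
            save_field(world.truth_drivers[var][decade], out / f"truth_{var}_{decade}.nc")
        for metric, fields in world.socio.items():
            save_field(fields[decade], out / f"socio_{metric}_{decade}.nc")
        for i in range(cfg.n_models):
            save_field(world.member_emission[i][decade], out / f"member{i:02d}_fire_carbon_emission_{decade}.nc")
    for var, static in world.truth_statics.items():
        save_field(static, out / f"truth_{var}_static.nc")
    for var, datasets in world.observations.items():
        for k, entry in enumerate(datasets):
            save_field(entry["annual"], out / f"obs_{var}_{k}.nc")
    save_region_map(world.regions, out / "regions.nc", out / "regions.csv")
    manifest = {
        "seed": cfg.seed,
        "resolution": cfg.spec.resolution,
        "n_models": cfg.n_models,
        "n_obs_datasets": cfg.n_obs_datasets,
        "decades": list(cfg.decades),
        "link": cfg.link,
        "planted_driver": cfg.planted_driver,
        "model_bias_amplitude": cfg.model_bias_amplitude,
        "link_perturbation": cfg.link_perturbation,
        "trend_spread": cfg.trend_spread,
        "obs_noise_sd": cfg.obs_noise_sd,
        "driver_trends": dict(cfg.driver_trends),
        "member_link_params": world.member_link_params,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
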