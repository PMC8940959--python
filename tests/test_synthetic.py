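"""Construction checks and statistical properties of the synthetic world."""

import numpy as np
import pytest

from mlec import GridSpec, WorldConfig, generate_socio, generate_world
from mlec.grid import region_totals
from mlec.synthetic import _BIASED_DRIVERS


def small_config(**kw):
    kw.setdefault("spec", GridSpec.global_grid(10.0))
    kw.setdefault("seed", 5)
    return WorldConfig(**kw)


def link_oracle(drivers, p):
    """Second, independent implementation of the nonlinear emission link."""

    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    fuel = (
        drivers["lai"] / (drivers["lai"] + p["lai_half"])
        * drivers["precipitation"] / (drivers["precipitation"] + p["pr_half"])
        * sig((drivers["temperature"] - p["t0"]) / p["t_scale"])
    )
    dry = sig((p["sm0"] - drivers["soil_moisture"]) / p["sm_scale"]) * sig(
        (p["rh0"] - drivers["rel_humidity"]) / p["rh_scale"]
    )
    flash = p["ign_base"] + (1 - p["ign_base"]) * sig(
        (drivers["flash_rate"] - p["flash0"]) / p["flash_scale"]
    )
    q = drivers["population"] / p["pop0"]
    ign = flash * (2 * q / (1 + q**2)) * (1 - p["lu_suppress"] * drivers["land_use"])
    spread = 0.5 + 0.5 * sig((drivers["wind"] - p["wind0"]) / p["wind_scale"])
    return np.clip(p["e0"] * fuel * dry * ign * spread, 0, None)


def drivers_of(world, source, decade):
    if source == "truth":
        d = {v: world.truth_drivers[v][decade].values for v in world.truth_drivers}
    else:
        d = {v: world.member_drivers[source][v][decade].values for v in world.truth_drivers}
    d["flash_rate"] = world.truth_statics["flash_rate"].values
    d["orography"] = world.truth_statics["orography"].values
    d["population"] = world.socio["population"][decade].values
    return d


class TestDeterminismAndStructure:
    def test_same_seed_bitwise_identical(self):
        w1 = generate_world(small_config())
        w2 = generate_world(small_config())
        assert np.array_equal(w1.truth_emission["2050s"].values, w2.truth_emission["2050s"].values)
        assert np.array_equal(
            w1.member_emission[3]["2090s"].values, w2.member_emission[3]["2090s"].values
        )
        assert w1.member_link_params == w2.member_link_params

    def test_different_seed_differs(self):
        w1 = generate_world(small_config(seed=5))
        w2 = generate_world(small_config(seed=6))
        assert not np.array_equal(w1.truth_emission["2000s"].values, w2.truth_emission["2000s"].values)

    def test_emissions_and_socio_nonnegative(self):
        w = generate_world(small_config())
        for decade in w.config.decades:
            assert (w.truth_emission[decade].values >= 0).all()
            for m in w.socio:
                assert (w.socio[m][decade].values >= 0).all()
        for i in range(w.config.n_models):
            assert (w.member_emission[i]["2090s"].values >= 0).all()

    def test_monthly_climatology_centred_on_annual(self):
        w = generate_world(small_config())
        for var in ("temperature", "precipitation"):
            months = np.mean([f.values for f in w.truth_monthly[var]], axis=0)
            annual = w.truth_drivers[var][w.hist_decade].values
            land = w.land_mask
            assert np.allclose(months[land], annual[land], atol=1e-9)


class TestTruthConstruction:
    def test_emission_matches_independent_link_evaluation(self):
        w = generate_world(small_config())
        for decade in ("2000s", "2040s"):
            expect = link_oracle(drivers_of(w, "truth", decade), w.link_params)
            got = w.truth_emission[decade].values
            assert np.allclose(got[w.land_mask], expect[w.land_mask], atol=1e-14)

    def test_zero_noise_observations_equal_truth(self):
        w = generate_world(small_config(obs_noise_sd=0.0))
        hist = w.hist_decade
        for var in ("temperature", "lai", "soil_moisture"):
            for ds in w.observations[var]:
                assert np.allclose(
                    ds["annual"].values[w.land_mask],
                    w.truth_drivers[var][hist].values[w.land_mask],
                )
        for ds in w.observations["fire_carbon_emission"]:
            assert np.allclose(
                ds["annual"].values[w.land_mask],
                w.truth_emission[hist].values[w.land_mask],
            )


class TestMembers:
    def test_zero_bias_zero_perturbation_members_equal_truth(self):
        w = generate_world(
            small_config(model_bias_amplitude=0.0, link_perturbation=0.0, trend_spread=0.0)
        )
        for i in range(w.config.n_models):
            assert np.allclose(
                w.member_emission[i]["2030s"].values, w.truth_emission["2030s"].values
            )

    def test_member_future_consistent_with_own_link(self):
        w = generate_world(small_config())
        for i in (0, 4):
            expect = link_oracle(drivers_of(w, i, "2070s"), w.member_link_params[i])
            got = w.member_emission[i]["2070s"].values
            assert np.allclose(got[w.land_mask], expect[w.land_mask], atol=1e-14)

    def test_ensemble_mean_driver_bias_shrinks_with_members(self):
        # smooth additive biases are symmetric, so the ensemble-mean bias of a
        # driver should be O(amplitude * sd / sqrt(n_models))
        amp, n_models = 0.5, 6
        rel = []
        for seed in range(20):
            cfg = small_config(seed=seed, n_models=n_models, model_bias_amplitude=amp)
            w = generate_world(cfg)
            land = w.land_mask
            truth = w.truth_drivers["temperature"][w.hist_decade].values[land]
            mean = np.mean(
                [w.member_drivers[i]["temperature"][w.hist_decade].values[land] for i in range(n_models)],
                axis=0,
            )
            rel.append(np.abs((mean - truth).mean()) / truth.std())
        assert np.mean(rel) < amp / np.sqrt(n_models) * 3

    def test_observations_inside_member_envelope(self):
        w = generate_world(WorldConfig(seed=2))  # default 5 deg settings
        land = w.land_mask
        hist = w.hist_decade
        fractions = []
        for var in _BIASED_DRIVERS:
            stack = np.stack(
                [w.member_drivers[i][var][hist].values[land] for i in range(w.config.n_models)]
            )
            lo, hi = stack.min(axis=0), stack.max(axis=0)
            for ds in w.observations[var]:
                obs = ds["annual"].values[land]
                fractions.append(np.mean((obs >= lo) & (obs <= hi)))
        assert np.mean(fractions) >= 0.95


class TestSocio:
    def test_zero_growth_fields_identical(self):
        cfg = small_config(
            socio_growth_ranges={"population": (0, 0), "gdp": (0, 0), "agricultural_area": (0, 0)}
        )
        fields, _ = generate_socio(cfg)
        for metric in fields:
            first = fields[metric][cfg.decades[0]].values
            for decade in cfg.decades:
                assert np.array_equal(fields[metric][decade].values, first)

    def test_prescribed_growth_is_geometric(self):
        w = generate_world(
            small_config(socio_growth_override={"population": {1: 0.10}})
        )
        totals = [
            region_totals(w.socio["population"][d], w.regions)[1] for d in w.config.decades
        ]
        base = totals[0]
        for d, t in enumerate(totals):
            assert np.isclose(t, base * 1.10**d, rtol=1e-9)

    def test_decadal_totals_match_bruteforce_accumulation(self):
        w = generate_world(small_config())
        metric = "gdp"
        rid = w.regions.region_id
        base = w.socio[metric][w.config.decades[0]].values
        for d, decade in enumerate(w.config.decades):
            expect = np.zeros_like(base)
            for r, rate in w.socio_growth[metric].items():
                sel = rid == r
                expect[sel] = base[sel] * (1 + rate) ** d
            got = w.socio[metric][decade].values
            assert np.allclose(got[rid > 0], expect[rid > 0], rtol=1e-12)
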