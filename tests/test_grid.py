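"""Grid geometry, regridding and aggregation against brute-force oracles."""

import numpy as np
import pytest

from mlec import (
    Field,
    GridSpec,
    RegionMap,
    cell_areas,
    global_total,
    load_field,
    regrid_bilinear,
    region_totals,
    save_field,
    zonal_band_totals,
)
from mlec.grid import EARTH_RADIUS_KM, load_region_map, save_region_map


def make_field(spec, values, mask=None, units="kg m-2 yr-1", var="fire_carbon_emission"):
    if mask is None:
        mask = np.ones(spec.shape, bool)
    return Field(spec, values, mask, var, units, "2000s")


def bilinear_oracle(field, target):
    """Independent pointwise evaluation of the bilinear formula with periodic
    longitude and clamped latitude."""
    src = field.spec
    out = np.empty(target.shape)
    for j, lat in enumerate(target.lat_centers):
        for i, lon in enumerate(target.lon_centers):
            la = np.clip(lat, src.lat_centers[0], src.lat_centers[-1])
            j0 = int(np.clip(np.searchsorted(src.lat_centers, la) - 1, 0, src.n_lat - 2))
            j1 = j0 + 1
            wj = (la - src.lat_centers[j0]) / (src.lat_centers[j1] - src.lat_centers[j0])
            wj = float(np.clip(wj, 0, 1))
            lo = (lon - src.lon_centers[0]) % 360.0 + src.lon_centers[0]
            i0 = int(np.searchsorted(src.lon_centers, lo, side="right") - 1) % src.n_lon
            i1 = (i0 + 1) % src.n_lon
            span = (src.lon_centers[i1] - src.lon_centers[i0]) % 360.0 or 360.0
            wi = ((lo - src.lon_centers[i0]) % 360.0) / span
            v = field.values
            out[j, i] = (1 - wj) * ((1 - wi) * v[j0, i0] + wi * v[j0, i1]) + wj * (
                (1 - wi) * v[j1, i0] + wi * v[j1, i1]
            )
    return out


class TestGridSpec:
    def test_global_grid_covers_globe(self):
        spec = GridSpec.global_grid(5.0)
        assert spec.shape == (36, 72)
        assert spec.lat_centers[0] == -87.5 and spec.lat_centers[-1] == 87.5
        assert spec.lon_centers[0] == -177.5

    def test_rejects_bad_specs(self):
        with pytest.raises(ValueError):
            GridSpec(2, 2, np.array([0.0, -1.0]), np.array([0.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            GridSpec(2, 2, np.array([-90.0, 0.0]), np.array([0.0, 90.0]), 90.0)


class TestRegrid:
    def test_constant_field_is_preserved(self):
        src = GridSpec.global_grid(10.0)
        dst = GridSpec.global_grid(4.0)
        f = make_field(src, np.full(src.shape, 3.7), units="1", var="x")
        out = regrid_bilinear(f, dst)
        assert np.allclose(out.values, 3.7, atol=1e-12)

    def test_exact_for_linear_in_latitude(self):
        src = GridSpec.global_grid(6.0)
        dst = GridSpec.global_grid(3.0)
        vals = np.broadcast_to(src.lat_centers[:, None], src.shape).copy()
        out = regrid_bilinear(make_field(src, vals, units="deg", var="lat"), dst)
        interior = (dst.lat_centers > src.lat_centers[0]) & (dst.lat_centers < src.lat_centers[-1])
        expect = np.broadcast_to(dst.lat_centers[:, None], dst.shape)
        assert np.allclose(out.values[interior], expect[interior], atol=1e-10)

    def test_matches_bruteforce_oracle(self, rng):
        src = GridSpec(4, 8, -67.5 + 45.0 * np.arange(4), -157.5 + 45.0 * np.arange(8), 45.0)
        dst = GridSpec(8, 16, -78.75 + 22.5 * np.arange(8), -168.75 + 22.5 * np.arange(16), 22.5)
        f = make_field(src, rng.standard_normal(src.shape), units="1", var="x")
        out = regrid_bilinear(f, dst)
        assert np.allclose(out.values, bilinear_oracle(f, dst), atol=1e-12)

    def test_mask_stays_binary_nearest_neighbour(self, rng):
        src = GridSpec.global_grid(10.0)
        dst = GridSpec.global_grid(5.0)
        mask = rng.random(src.shape) > 0.5
        f = make_field(src, rng.random(src.shape), mask=mask, units="1", var="x")
        out = regrid_bilinear(f, dst)
        assert out.mask.dtype == bool
        assert out.mask.sum() > 0

    def test_total_roughly_conserved_for_smooth_fields(self):
        from scipy.ndimage import gaussian_filter

        src = GridSpec.global_grid(2.0)
        r = np.random.default_rng(0)
        vals = 1.0 + 0.3 * gaussian_filter(r.standard_normal(src.shape), 4, mode=("nearest", "wrap"))
        f = make_field(src, vals)
        out = regrid_bilinear(f, GridSpec.global_grid(0.25))
        assert abs(global_total(out) / global_total(f) - 1) < 0.02


class TestAreasAndTotals:
    def test_areas_sum_to_sphere(self):
        for res in (10.0, 7.5, 2.5):
            spec = GridSpec.global_grid(res)
            assert np.isclose(cell_areas(spec).sum(), 4 * np.pi * EARTH_RADIUS_KM**2, rtol=1e-9)
        assert np.isclose(cell_areas(GridSpec.global_grid(5.0)).sum(), 5.10064e8, rtol=1e-5)

    def test_area_latitude_ratio(self):
        spec = GridSpec.global_grid(1.0)
        areas = cell_areas(spec)
        j0 = np.argmin(np.abs(spec.lat_centers - 0.5))
        j60 = np.argmin(np.abs(spec.lat_centers - 60.5))
        edges = np.deg2rad(spec.lat_edges())
        expect = (np.sin(edges[j0 + 1]) - np.sin(edges[j0])) / (np.sin(edges[j60 + 1]) - np.sin(edges[j60]))
        assert np.isclose(areas[j0, 0] / areas[j60, 0], expect, rtol=1e-12)

    def test_areas_match_quadrature(self, rng):
        spec = GridSpec.global_grid(12.0)
        areas = cell_areas(spec)
        edges = spec.lat_edges()
        # numeric integration of R^2 cos(phi) dphi dlambda over one cell per row
        for j in range(spec.n_lat):
            phi = np.linspace(np.deg2rad(edges[j]), np.deg2rad(edges[j + 1]), 20001)
            integral = np.trapezoid(np.cos(phi), phi) * np.deg2rad(spec.resolution)
            assert np.isclose(areas[j, 0], EARTH_RADIUS_KM**2 * integral, rtol=1e-7)

    def test_global_total_trivials_and_oracle(self, rng):
        spec = GridSpec.global_grid(10.0)
        zero = make_field(spec, np.zeros(spec.shape))
        assert global_total(zero) == 0.0
        mask = rng.random(spec.shape) > 0.4
        ones = make_field(spec, np.ones(spec.shape), mask=mask)
        area_km2 = cell_areas(spec)[mask].sum()
        assert np.isclose(global_total(ones), area_km2 * 1e-3, rtol=1e-12)
        f = make_field(spec, rng.random(spec.shape), mask=mask)
        brute = sum(
            f.values[j, i] * cell_areas(spec)[j, i] * 1e6 / 1e9
            for j in range(spec.n_lat)
            for i in range(spec.n_lon)
            if mask[j, i]
        )
        assert np.isclose(global_total(f), brute, rtol=1e-12)

    def test_non_flux_units_rejected(self):
        spec = GridSpec.global_grid(10.0)
        f = make_field(spec, np.ones(spec.shape), units="person", var="population")
        with pytest.raises(ValueError, match="flux"):
            global_total(f)


class TestZonalAndRegional:
    def test_bands_partition_global_total(self, rng):
        spec = GridSpec.global_grid(5.0)
        f = make_field(spec, rng.random(spec.shape), mask=rng.random(spec.shape) > 0.3)
        bands = zonal_band_totals(f, 10.0)
        assert np.isclose(bands.sum(), global_total(f), rtol=1e-10)

    def test_point_mass_lands_in_correct_band(self):
        spec = GridSpec.global_grid(0.25)
        vals = np.zeros(spec.shape)
        j = int(np.argmin(np.abs(spec.lat_centers - 4.875)))
        assert np.isclose(spec.lat_centers[j], 4.875)
        vals[j, 100] = 1.0
        bands = zonal_band_totals(make_field(spec, vals), 10.0)
        assert bands["0..10"] == pytest.approx(global_total(make_field(spec, vals)))
        assert (bands.drop("0..10") == 0).all()

    def test_band_totals_match_bruteforce(self, rng):
        spec = GridSpec.global_grid(6.0)
        f = make_field(spec, rng.random(spec.shape), mask=rng.random(spec.shape) > 0.5)
        bands = zonal_band_totals(f, 30.0)
        for b, (lo, hi) in enumerate(zip(range(-90, 90, 30), range(-60, 91, 30))):
            rows = (spec.lat_centers >= lo) & (spec.lat_centers < hi)
            sub = make_field(spec, f.values * rows[:, None], mask=f.mask & rows[:, None])
            assert np.isclose(bands.iloc[b], global_total(sub), rtol=1e-10)

    def test_region_totals_partition_and_oracle(self, rng):
        spec = GridSpec.global_grid(10.0)
        mask = rng.random(spec.shape) > 0.4
        f = make_field(spec, rng.random(spec.shape), mask=mask)
        rid = np.where(mask, rng.integers(1, 4, spec.shape), 0)
        regions = RegionMap(spec, rid, {1: "a", 2: "b", 3: "c"})
        totals = region_totals(f, regions)
        masked_total = global_total(make_field(spec, f.values * (rid > 0), mask=mask & (rid > 0)))
        assert np.isclose(sum(totals.values()), masked_total, rtol=1e-10)
        for r in (1, 2, 3):
            sub = make_field(spec, f.values * (rid == r), mask=mask & (rid == r))
            assert np.isclose(totals[r], global_total(sub), rtol=1e-10)

    def test_single_region_covering_mask_equals_global(self, rng):
        spec = GridSpec.global_grid(10.0)
        mask = rng.random(spec.shape) > 0.4
        f = make_field(spec, rng.random(spec.shape), mask=mask)
        regions = RegionMap(spec, mask.astype(int), {1: "world"})
        assert np.isclose(region_totals(f, regions)[1], global_total(f), rtol=1e-12)


class TestIO:
    def test_field_roundtrip(self, tmp_path, rng):
        spec = GridSpec.global_grid(10.0)
        f = make_field(spec, rng.random(spec.shape), mask=rng.random(spec.shape) > 0.5)
        p = tmp_path / "f.nc"
        save_field(f, p)
        g = load_field(p)
        assert np.allclose(f.values, g.values)
        assert np.array_equal(f.mask, g.mask)
        assert g.units == f.units and g.time_tag == f.time_tag

    def test_region_map_roundtrip(self, tmp_path, rng):
        spec = GridSpec.global_grid(10.0)
        rid = rng.integers(0, 3, spec.shape)
        rm = RegionMap(spec, rid, {1: "a", 2: "b"})
        save_region_map(rm, tmp_path / "r.nc", tmp_path / "r.csv")
        back = load_region_map(tmp_path / "r.nc", tmp_path / "r.csv")
        assert np.array_equal(back.region_id, rid)
        assert back.names == {1: "a", 2: "b"}
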