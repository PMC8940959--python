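"""Grid geometry, regridding, masking and spatial aggregation.

Conventions
-----------
Cell-centred regular lat/lon grids: latitude strictly ascending in (-90, 90),
longitude strictly ascending in [-180, 180), fields stored row-major as
``(n_lat, n_lon)`` arrays.  Longitude is treated as periodic; interpolation
poleward of the first/last latitude row clamps to the nearest row.

Totals of flux-density fields (e.g. fire carbon emission in kg m-2 yr-1) are
area-integrated on the sphere and reported in Tg yr-1; non-flux fields (e.g.
exposure products) are summed per cell without area weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dfield, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "GridSpec",
    "Field",
    "RegionMap",
    "regrid_bilinear",
    "cell_areas",
    "global_total",
    "field_sum",
    "zonal_band_totals",
    "region_totals",
    "save_field",
    "load_field",
    "save_region_map",
    "load_region_map",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular global lat/lon grid of cell centres."""

    n_lat: int
    n_lon: int
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        if self.n_lat * self.n_lon <= 0:
            raise ValueError("grid must contain at least one cell")
        if lat.shape != (self.n_lat,) or lon.shape != (self.n_lon,):
            raise ValueError("centre arrays inconsistent with n_lat/n_lon")
        if np.any(np.diff(lat) <= 0) or np.any(np.diff(lon) <= 0):
            raise ValueError("centres must be strictly increasing")
        if lat[0] <= -90 or lat[-1] >= 90:
            raise ValueError("latitude centres must lie in (-90, 90)")
        for centers in (lat, lon):
            if centers.size > 1 and not np.allclose(
                np.diff(centers), self.resolution, rtol=0, atol=1e-9
            ):
                raise ValueError("centres must be equally spaced at `resolution`")

    @classmethod
    def global_grid(cls, resolution: float) -> "GridSpec":
        n_lat = int(round(180.0 / resolution))
        n_lon = int(round(360.0 / resolution))
        lat = -90.0 + resolution * (np.arange(n_lat) + 0.5)
        lon = -180.0 + resolution * (np.arange(n_lon) + 0.5)
        return cls(n_lat, n_lon, lat, lon, resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def lat_edges(self) -> np.ndarray:
        e = np.concatenate(
            [
                self.lat_centers - self.resolution / 2.0,
                [self.lat_centers[-1] + self.resolution / 2.0],
            ]
        )
        return np.clip(e, -90.0, 90.0)

    def __eq__(self, other: object) -> bool:  # array fields break default eq
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.lat_centers, other.lat_centers)
            and np.allclose(self.lon_centers, other.lon_centers)
        )

    def __hash__(self) -> int:
        return hash((self.n_lat, self.n_lon, float(self.resolution)))


@dataclass
class Field:
    """One gridded variable for one decade (or calendar month)."""

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray
    variable_id: str
    units: str
    time_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.spec.shape or self.mask.shape != self.spec.shape:
            raise ValueError("values/mask shape does not match grid spec")
        if not self.units:
            raise ValueError("units string must be nonempty")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError(f"non-finite values inside mask for {self.variable_id!r}")

    def copy_with(self, **kwargs) -> "Field":
        return replace(self, **kwargs)

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def is_flux_density(self) -> bool:
        u = self.units.replace("^", "").replace("**", "")
        return "m-2" in u or "m⁻²" in u


@dataclass
class RegionMap:
    """Integer region raster (0 = no region) with an id -> name table."""

    spec: GridSpec
    region_id: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.region_id.shape != self.spec.shape:
            raise ValueError("region raster shape does not match grid spec")
        present = set(np.unique(self.region_id)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"region ids without names: {sorted(missing)}")

    @property
    def ids(self) -> list[int]:
        return sorted(set(np.unique(self.region_id)) - {0})


# ---------------------------------------------------------------------------
# regridding


def _axis_weights(src: np.ndarray, dst: np.ndarray, periodic: bool):
    """Indices (i0, i1) and weight w of the two bracketing source centres for
    each destination centre; clamped at the ends unless periodic."""
    n = src.size
    if periodic:
        # unwrap destination into [src[0], src[0] + 360)
        d = np.mod(dst - src[0], 360.0) + src[0]
        idx = np.searchsorted(src, d, side="right") - 1
        i0 = np.mod(idx, n)
        i1 = np.mod(idx + 1, n)
        x0 = src[i0]
        span = np.mod(src[i1] - x0, 360.0)
        span[span == 0] = 360.0
        w = np.mod(d - x0, 360.0) / span
        return i0, i1, w
    idx = np.clip(np.searchsorted(src, dst, side="right") - 1, 0, n - 2)
    i0, i1 = idx, idx + 1
    w = (dst - src[i0]) / (src[i1] - src[i0])
    return i0, i1, np.clip(w, 0.0, 1.0)  # clamp beyond the outer rows


def regrid_bilinear(field: Field, target: GridSpec) -> Field:
    """Bilinear interpolation onto ``target``; mask by nearest neighbour.

    Longitude is periodic; latitudes outside the source range clamp to the
    nearest row.  A target cell is valid iff its nearest source cell is valid.
    """
    src = field.spec
    if src.n_lat < 2 or src.n_lon < 2:
        raise ValueError("source grid needs at least 2 points per axis")
    if target.lat_centers[0] > src.lat_centers[-1] + src.resolution or (
        target.lat_centers[-1] < src.lat_centers[0] - src.resolution
    ):
        raise ValueError(
            "grids do not overlap: source lat "
            f"[{src.lat_centers[0]}, {src.lat_centers[-1]}], target lat "
            f"[{target.lat_centers[0]}, {target.lat_centers[-1]}]"
        )
    j0, j1, wj = _axis_weights(src.lat_centers, target.lat_centers, periodic=False)
    i0, i1, wi = _axis_weights(src.lon_centers, target.lon_centers, periodic=True)
    v = field.values
    wj = wj[:, None]
    wi = wi[None, :]
    out = (
        (1 - wj) * ((1 - wi) * v[np.ix_(j0, i0)] + wi * v[np.ix_(j0, i1)])
        + wj * ((1 - wi) * v[np.ix_(j1, i0)] + wi * v[np.ix_(j1, i1)])
    )
    # nearest-neighbour mask transfer keeps the mask binary
    jn = np.where(wj[:, 0] < 0.5, j0, j1)
    inn = np.where(wi[0, :] < 0.5, i0, i1)
    mask = field.mask[np.ix_(jn, inn)]
    out = np.where(mask, out, np.where(np.isfinite(out), out, 0.0))
    return Field(target, out, mask, field.variable_id, field.units, field.time_tag)


# ---------------------------------------------------------------------------
# areas and totals


def cell_areas(spec: GridSpec, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Exact spherical-zone cell areas in km^2; sums to 4*pi*R^2 on a global grid."""
    edges = np.deg2rad(spec.lat_edges())
    zone = np.sin(edges[1:]) - np.sin(edges[:-1])
    dlon = np.deg2rad(spec.resolution)
    return (radius_km**2) * dlon * zone[:, None] * np.ones((1, spec.n_lon))


def _cell_totals_tg(field: Field, radius_km: float) -> np.ndarray:
    """Per-cell mass totals (Tg yr-1) of a flux-density field; 0 outside mask."""
    if not field.is_flux_density():
        raise ValueError(
            f"global_total needs a per-area flux density, got units {field.units!r}"
        )
    areas_m2 = cell_areas(field.spec, radius_km) * 1e6
    return np.where(field.mask, field.values, 0.0) * areas_m2 / 1e9


def global_total(field: Field, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Area-integrated global total of a flux-density field, in Tg yr-1."""
    return float(_cell_totals_tg(field, radius_km).sum())


def field_sum(field: Field) -> float:
    """Plain sum over unmasked cells (for non-flux quantities such as exposure)."""
    return float(np.where(field.mask, field.values, 0.0).sum())


def zonal_band_totals(
    field: Field, band_width: float = 10.0, radius_km: float = EARTH_RADIUS_KM
) -> pd.Series:
    """Totals (Tg yr-1) in half-open latitude bands [south, north)."""
    if abs((180.0 / band_width) - round(180.0 / band_width)) > 1e-9:
        raise ValueError("band_width must divide 180")
    n_bands = int(round(180.0 / band_width))
    edges = -90.0 + band_width * np.arange(n_bands + 1)
    idx = np.clip(
        np.floor((field.spec.lat_centers + 90.0) / band_width).astype(int),
        0,
        n_bands - 1,
    )
    per_cell = _cell_totals_tg(field, radius_km)
    totals = np.zeros(n_bands)
    np.add.at(totals, idx, per_cell.sum(axis=1))
    labels = [f"{edges[i]:.0f}..{edges[i+1]:.0f}" for i in range(n_bands)]
    return pd.Series(totals, index=labels, name="total_tg")


def region_totals(
    field: Field,
    regions: RegionMap,
    radius_km: float = EARTH_RADIUS_KM,
    per_area: bool | None = None,
) -> dict[int, float]:
    """Per-region totals: area-integrated (Tg) for flux densities, else plain sums.

    ``per_area`` overrides the unit-based inference (exposure products carry
    per-area emission units but total as plain per-cell sums).
    """
    if regions.spec != field.spec:
        raise ValueError("region map grid does not match field grid")
    if per_area is None:
        per_area = field.is_flux_density()
    if per_area:
        per_cell = _cell_totals_tg(field, radius_km)
    else:
        per_cell = np.where(field.mask, field.values, 0.0)
    out: dict[int, float] = {}
    for rid in regions.ids:
        out[rid] = float(per_cell[regions.region_id == rid].sum())
    return out


# ---------------------------------------------------------------------------
# NetCDF I/O (classic NetCDF-3 via the scipy backend)


def field_to_dataset(field: Field) -> xr.Dataset:
    ds = xr.Dataset(
        {
            field.variable_id: (("lat", "lon"), field.values),
            "mask": (("lat", "lon"), field.mask.astype(np.int8)),
        },
        coords={"lat": field.spec.lat_centers, "lon": field.spec.lon_centers},
    )
    ds[field.variable_id].attrs["units"] = field.units
    ds.attrs.update(
        {
            "time_tag": field.time_tag,
            "resolution": field.spec.resolution,
            "grid_convention": "cell centers, lat ascending, lon in [-180, 180)",
        }
    )
    return ds


def save_field(field: Field, path: str | Path) -> None:
    field_to_dataset(field).to_netcdf(path, engine="scipy")


def load_field(path: str | Path, variable_id: str | None = None) -> Field:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if variable_id is None:
        variable_id = next(v for v in ds.data_vars if v != "mask")
    lat = ds["lat"].values
    lon = ds["lon"].values
    res = float(ds.attrs.get("resolution", np.diff(lat).mean()))
    spec = GridSpec(lat.size, lon.size, lat, lon, res)
    return Field(
        spec,
        ds[variable_id].values,
        ds["mask"].values.astype(bool),
        variable_id,
        ds[variable_id].attrs.get("units", "1"),
        str(ds.attrs.get("time_tag", "")),
    )


def save_region_map(regions: RegionMap, nc_path: str | Path, csv_path: str | Path) -> None:
    ds = xr.Dataset(
        {"region_id": (("lat", "lon"), regions.region_id.astype(np.int32))},
        coords={"lat": regions.spec.lat_centers, "lon": regions.spec.lon_centers},
    )
    ds.attrs["resolution"] = regions.spec.resolution
    ds.to_netcdf(nc_path, engine="scipy")
    pd.DataFrame(
        {"id": list(regions.names), "name": list(regions.names.values())}
    ).to_csv(csv_path, index=False)


def load_region_map(nc_path: str | Path, csv_path: str | Path) -> RegionMap:
    with xr.open_dataset(nc_path, engine="scipy") as ds:
        ds = ds.load()
    lat = ds["lat"].values
    lon = ds["lon"].values
    res = float(ds.attrs.get("resolution", np.diff(lat).mean()))
    spec = GridSpec(lat.size, lon.size, lat, lon, res)
    table = pd.read_csv(csv_path)
    names = dict(zip(table["id"].astype(int), table["name"].astype(str)))
    return RegionMap(spec, ds["region_id"].values, names)
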