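"""Spatial-sample training tables and observation predictor matrices.

Each atmospheric/terrestrial variable contributes 13 encodings — the decadal
annual mean plus the climatology of each of the 12 calendar months — while
terrain, lightning and decadal socioeconomic products contribute one encoding
each.  Rows of a table are the unmasked land cells of the grid (the "spatial
sample"); the target vector is a source's fire carbon emission in the target
decade.  Feature ordering is deterministic: variables sorted alphabetically,
encodings in the order annual, Jan..Dec, static.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ._rng import child_seed, rng
from .grid import Field

__all__ = [
    "MONTH_NAMES",
    "PredictorSpec",
    "TrainingTable",
    "climatology_features",
    "build_training_table",
    "kfold_split",
    "nominal_fold_sizes",
    "build_observation_matrix",
]

MONTH_NAMES = (
    "jan", "feb", "mar", "apr", "may", "jun",
    "jul", "aug", "sep", "oct", "nov", "dec",
)
_ENCODINGS_DYNAMIC = ("annual",) + MONTH_NAMES


@dataclass(frozen=True)
class PredictorSpec:
    """Which variables enter the table and with which decades."""

    dynamic_variables: tuple[str, ...]
    static_variables: tuple[str, ...]
    target_variable: str = "fire_carbon_emission"
    historical_decade: str = "2000s"
    target_decade: str = "2010s"

    def __post_init__(self) -> None:
        names = list(self.dynamic_variables) + list(self.static_variables)
        if len(names) != len(set(names)):
            raise ValueError("duplicate predictor variable names")

    @property
    def n_features(self) -> int:
        return 13 * len(self.dynamic_variables) + len(self.static_variables)

    def feature_meta(self) -> list[tuple[str, str]]:
        meta: list[tuple[str, str]] = []
        for var in sorted(self.dynamic_variables):
            meta.extend((var, enc) for enc in _ENCODINGS_DYNAMIC)
        meta.extend((var, "static") for var in sorted(self.static_variables))
        return meta


@dataclass
class TrainingTable:
    """Spatial-sample design matrix with target and provenance."""

    X: np.ndarray
    y: np.ndarray
    feature_meta: list[tuple[str, str]]
    sample_coords: np.ndarray  # (n, 2) lat, lon
    provenance: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y sample counts differ")
        if self.X.shape[1] != len(self.feature_meta):
            raise ValueError("feature_meta length does not match X")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("training table contains missing values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def without_variable(self, variable: str) -> "TrainingTable":
        keep = [i for i, (v, _) in enumerate(self.feature_meta) if v != variable]
        if len(keep) == len(self.feature_meta):
            raise KeyError(f"variable {variable!r} not in table")
        return TrainingTable(
            self.X[:, keep],
            self.y,
            [self.feature_meta[i] for i in keep],
            self.sample_coords,
            self.provenance,
        )

    # ------------------------------------------------------------------
    def to_csv(self, csv_path: str | Path, meta_path: str | Path) -> None:
        cols = [f"{v}.{e}" for v, e in self.feature_meta]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "lat", self.sample_coords[:, 0])
        df.insert(1, "lon", self.sample_coords[:, 1])
        df["target"] = self.y
        df.to_csv(csv_path, index=False)
        Path(meta_path).write_text(
            json.dumps({"feature_meta": self.feature_meta, "provenance": self.provenance})
        )

    @classmethod
    def from_csv(cls, csv_path: str | Path, meta_path: str | Path) -> "TrainingTable":
        meta = json.loads(Path(meta_path).read_text())
        fm = [tuple(x) for x in meta["feature_meta"]]
        df = pd.read_csv(csv_path)
        cols = [f"{v}.{e}" for v, e in fm]
        return cls(
            df[cols].to_numpy(),
            df["target"].to_numpy(),
            fm,
            df[["lat", "lon"]].to_numpy(),
            meta["provenance"],
        )


# ---------------------------------------------------------------------------


def climatology_features(monthly: Sequence[Field]) -> list[Field]:
    """13 fields from 120 monthly fields: 12 calendar-month means + annual mean.

    The input is ordered January of year 1 .. December of year 10; element i
    belongs to calendar month ``i % 12``.
    """
    if len(monthly) != 120:
        raise ValueError(f"need 120 monthly fields for one decade, got {len(monthly)}")
    ref = monthly[0]
    out = []
    for m in range(12):
        vals = np.mean([monthly[i].values for i in range(m, 120, 12)], axis=0)
        out.append(ref.copy_with(values=vals, time_tag=f"clim-{MONTH_NAMES[m]}"))
    annual = np.mean([f.values for f in monthly], axis=0)
    out.append(ref.copy_with(values=annual, time_tag="clim-annual"))
    return out


def _column(entry: Mapping, encoding: str, mask: np.ndarray) -> np.ndarray:
    if encoding == "annual" or encoding == "static":
        return entry["annual"].values[mask]
    if entry.get("monthly") is None:
        raise ValueError("monthly climatology required but not available")
    return entry["monthly"][MONTH_NAMES.index(encoding)].values[mask]


def build_training_table(
    predictors: Mapping[str, Mapping],
    target: Field,
    spec: PredictorSpec,
    mask: np.ndarray,
    provenance: str,
) -> TrainingTable:
    """Assemble one row per unmasked cell from per-variable predictor fields.

    ``predictors`` maps variable name to ``{"annual": Field, "monthly":
    list[Field] | None}`` (monthly required for dynamic variables).
    """
    for var in list(spec.dynamic_variables) + list(spec.static_variables):
        if var not in predictors:
            raise KeyError(f"missing predictor variable {var!r}")
    mask = np.asarray(mask, dtype=bool)
    meta = spec.feature_meta()
    cols = [_column(predictors[v], enc, mask) for v, enc in meta]
    X = np.column_stack(cols)
    grid = target.spec
    lats, lons = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
    coords = np.column_stack([lats[mask], lons[mask]])
    return TrainingTable(X, target.values[mask], meta, coords, provenance)


def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic shuffled k-fold assignment (fold index per sample)."""
    if n < k:
        raise ValueError(f"cannot split n={n} samples into k={k} folds")
    folds = np.empty(n, dtype=int)
    kf = KFold(n_splits=k, shuffle=True, random_state=child_seed(seed, "kfold") % (2**32))
    for f, (_, test_idx) in enumerate(kf.split(np.arange(n))):
        folds[test_idx] = f
    return folds


def nominal_fold_sizes(n: int, k: int = 10) -> tuple[int, int]:
    """(fitting, validation) sample counts of one fold of a k-fold split."""
    return n - n // k, n // k


def build_observation_matrix(
    observations: Mapping[str, Sequence[Mapping]],
    spec: PredictorSpec,
    mask: np.ndarray,
    cap: int = 16,
    seed: int = 0,
) -> list[tuple[np.ndarray, str]]:
    """Observation design matrices, one per dataset combination.

    Each combination picks one observational dataset per variable; the full
    Cartesian product is enumerated when it has at most ``cap`` members,
    otherwise ``cap`` distinct combinations are drawn with the seed.
    """
    variables = sorted(list(spec.dynamic_variables) + list(spec.static_variables))
    counts = []
    for var in variables:
        ds = observations.get(var)
        if not ds:
            raise ValueError(f"no observational dataset for variable {var!r}")
        counts.append(len(ds))
    total = int(np.prod(counts))
    if total <= cap:
        picks = list(itertools.product(*[range(c) for c in counts]))
    else:
        r = rng(seed, "obs-combos")
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < cap:
            chosen.add(tuple(int(r.integers(c)) for c in counts))
        picks = sorted(chosen)
    mask = np.asarray(mask, dtype=bool)
    meta = spec.feature_meta()
    out = []
    for pick in picks:
        sel = dict(zip(variables, pick))
        cols = [_column(observations[v][sel[v]], enc, mask) for v, enc in meta]
        label = "|".join(f"{v}:{sel[v]}" for v in variables)
        out.append((np.column_stack(cols), label))
    return out
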