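"""Core containers for harmonized subnational crop statistics.

The canonical tabular unit is one observation of a crop statistic for a
(geographic unit, product, season, production system, year) combination,
carried as a row of a pandas DataFrame in the fixed 16-column schema
(:data:`CANONICAL_COLUMNS`).  Time-series views of one such combination are
:class:`StatSeries`; administrative geometries are :class:`AdminUnit`; the
cropland density surface used for dasymetric weights is
:class:`CroplandRaster`.

Missing statistics are NaN throughout — never zero.  "Not collected" and
"zero production" are distinct states in subnational reporting and the
distinction is preserved end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .errors import InvariantError

#: Fixed column order of the harmonized tabular dataset.
CANONICAL_COLUMNS = [
    "fnid",
    "country",
    "country_code",
    "admin_1",
    "admin_2",
    "product",
    "season_name",
    "planting_year",
    "planting_month",
    "harvest_year",
    "harvest_month",
    "crop_production_system",
    "qc_flag",
    "area",
    "production",
    "yield",
]

#: Columns identifying one statistical time-series.
SERIES_KEY = ["fnid", "product", "season_name", "crop_production_system"]

#: Numeric statistic columns (hectares, metric tonnes, tonnes per hectare).
STAT_COLUMNS = ["area", "production", "yield"]

FLAG_NONE = 0
FLAG_OUTLIER = 1
FLAG_LOW_VARIANCE = 2

#: Relative tolerance for the yield == production / area consistency check.
YIELD_RTOL = 1e-6


@dataclass
class StatSeries:
    """Year-indexed production/area/yield triple for one series key.

    Parameters
    ----------
    key
        ``(fnid, product, season_name, crop_production_system)``.
    years
        Strictly increasing calendar years (harvest years).
    production, area, yields
        Statistic vectors aligned to ``years``; NaN marks missing.
    """

    key: tuple
    years: np.ndarray
    production: np.ndarray
    area: np.ndarray
    yields: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for name in ("production", "area", "yields"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.years)
        if any(len(getattr(self, s)) != n for s in ("production", "area", "yields")):
            raise InvariantError(f"series {self.key}: vector lengths differ")
        if n > 1 and not np.all(np.diff(self.years) > 0):
            raise InvariantError(f"series {self.key}: years not strictly increasing")

    def __len__(self) -> int:
        return len(self.years)

    @classmethod
    def from_frame(cls, key: tuple, frame: pd.DataFrame) -> "StatSeries":
        """Build a series from rows of one (fnid, product, season, system) group."""
        g = frame.sort_values("harvest_year")
        years = g["harvest_year"].to_numpy(dtype=int)
        if len(np.unique(years)) != len(years):
            raise InvariantError(
                f"series {key}: duplicate harvest_year values {sorted(years)}"
            )
        return cls(
            key=key,
            years=years,
            production=g["production"].to_numpy(dtype=float),
            area=g["area"].to_numpy(dtype=float),
            yields=g["yield"].to_numpy(dtype=float),
        )


def iter_series(records: pd.DataFrame) -> Iterator[tuple[tuple, StatSeries, pd.Index]]:
    """Iterate (key, StatSeries, row index) over a records table.

    Groups by :data:`SERIES_KEY` with NaN-safe grouping; the returned index
    is ordered by harvest_year and aligns with the series vectors, so flags
    or values computed on the series can be written back row-wise.
    """
    for key, g in records.groupby(SERIES_KEY, dropna=False, sort=True):
        g = g.sort_values("harvest_year")
        yield key, StatSeries.from_frame(key, g), g.index


@dataclass
class AdminUnit:
    """One administrative unit polygon at a specific boundary vintage."""

    fnid: str
    country_code: str
    level: int
    name: str
    geometry: BaseGeometry
    vintage: str = ""
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise InvariantError(f"admin unit {self.fnid}: empty geometry")
        if self.level not in (1, 2):
            raise InvariantError(f"admin unit {self.fnid}: level must be 1 or 2")

    @property
    def area(self) -> float:
        return self.geometry.area


@dataclass
class CroplandRaster:
    """Gridded cropland area (hectares per cell), north-up rectilinear grid.

    ``transform`` is ``(x0, y0, dx, dy)``: the top-left corner of cell
    ``[0, 0]`` is at ``(x0, y0)``; x increases by ``dx`` per column and y
    *decreases* by ``dy`` per row (both positive).
    """

    values: np.ndarray
    transform: tuple[float, float, float, float]
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvariantError("raster values must be a 2-D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvariantError("raster cells must be finite and >= 0")
        x0, y0, dx, dy = self.transform
        if dx <= 0 or dy <= 0:
            raise InvariantError("raster cell sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        x0, y0, dx, dy = self.transform
        nrow, ncol = self.values.shape
        return (x0, y0 - nrow * dy, x0 + ncol * dx, y0)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x0, y0, dx, dy = self.transform
        return (x0 + col * dx, y0 - (row + 1) * dy, x0 + (col + 1) * dx, y0 - row * dy)


def check_record_invariants(records: pd.DataFrame) -> pd.DataFrame:
    """Validate per-row invariants; return a violation report (one row each).

    Checked: qc_flag in {0, 1, 2}; months in 1..12; harvest_year >=
    planting_year; statistics >= 0 where present; yield consistent with
    production / area within :data:`YIELD_RTOL` where all three are present
    and area > 0.
    """
    problems: list[dict] = []

    def add(mask: pd.Series, message: str) -> None:
        for idx in records.index[mask.fillna(False)]:
            problems.append({"row": idx, "problem": message})

    add(~records["qc_flag"].isin([0, 1, 2]), "qc_flag not in {0, 1, 2}")
    for col in ("planting_month", "harvest_month"):
        add(~records[col].between(1, 12), f"{col} outside 1..12")
    add(
        records["harvest_year"] < records["planting_year"],
        "harvest_year earlier than planting_year",
    )
    for col in STAT_COLUMNS:
        add(records[col] < 0, f"negative {col}")

    area = records["area"].astype(float)
    prod = records["production"].astype(float)
    yld = records["yield"].astype(float)
    have_all = area.notna() & prod.notna() & yld.notna() & (area > 0)
    implied = prod[have_all] / area[have_all]
    bad = ~np.isclose(yld[have_all], implied, rtol=YIELD_RTOL, atol=0.0)
    for idx in records.index[have_all][bad]:
        problems.append(
            {"row": idx, "problem": "yield inconsistent with production/area"}
        )

    return pd.DataFrame(problems, columns=["row", "problem"])
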