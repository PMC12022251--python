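"""Standardization: sub-crop re-aggregation and coverage-gated spatial
aggregation.

Reported crop categories drift over time (a single "millet" category later
split into "pearl millet" and "finger millet", say); a user-supplied
mapping folds sub-crops back into continuous canonical categories, summing
production and area and recomputing yield.

When reporting moves to a coarser administrative level, fine-level series
are summed into their parent units — but only for years in which the
reporting subunits account for at least ``min_coverage`` (default 50%) of
the parent's expected production.  Expected production per subunit-year is
a smoothed climatology: a normalized Gaussian kernel over observed years
(kernel sd 3 years by default), which is defined at unobserved years too
and so gives a stable denominator under intermittent reporting.  Years
failing the gate are marked missing rather than reported low.

Season heterogeneity is deliberately preserved: "annual" and "short
rains" records never merge here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvariantError, SchemaError
from .model import CANONICAL_COLUMNS, FLAG_NONE, StatSeries


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian climatology filter: kernel sd in years, truncation in sds."""

    kernel_sd: float = 3.0
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.kernel_sd <= 0:
            raise InvariantError("kernel_sd must be > 0")


@dataclass(frozen=True)
class CoverageParams:
    """Minimum share of expected production required to aggregate."""

    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise InvariantError("min_coverage must be in (0, 1]")


_GROUP_META = [
    "fnid", "country", "country_code", "admin_1", "admin_2",
    "season_name", "crop_production_system",
    "planting_year", "planting_month", "harvest_year", "harvest_month",
]


def _recompute_yield(df: pd.DataFrame) -> pd.Series:
    area = df["area"].astype(float)
    prod = df["production"].astype(float)
    out = pd.Series(np.nan, index=df.index, dtype=float)
    ok = area.notna() & (area > 0) & prod.notna()
    out[ok] = prod[ok] / area[ok]
    return out


def aggregate_subcrops(
    records: pd.DataFrame,
    mapping: dict[str, str],
    strict: bool = False,
) -> pd.DataFrame:
    """Fold sub-crop categories into canonical products.

    Within each (unit, season, system, canonical product, year) cell,
    production and area are summed (missing contributes nothing; all
    missing stays missing) and yield is recomputed.  Products absent from
    the mapping pass through unchanged (strict mode raises instead).
    QC flags are reset to 0: they referred to the pre-aggregation series.
    """
    present = set(records["product"].dropna())
    unmapped = sorted(present - set(mapping))
    if unmapped and strict:
        raise SchemaError(f"crop mapping lacks product(s): {', '.join(unmapped)}")
    out = records.copy()
    out["product"] = out["product"].map(lambda p: mapping.get(p, p))

    grouped = out.groupby(
        ["fnid", "product", "season_name", "crop_production_system", "harvest_year"],
        dropna=False,
        sort=False,
    )
    if grouped.ngroups == len(out):
        return out  # nothing actually merged; identity mapping round-trip

    parts = []
    for _, g in grouped:
        row = g.iloc[0][CANONICAL_COLUMNS].copy()
        row["production"] = g["production"].sum(min_count=1)
        row["area"] = g["area"].sum(min_count=1)
        row["qc_flag"] = FLAG_NONE
        parts.append(row)
    merged = pd.DataFrame(parts).reset_index(drop=True)
    merged["yield"] = _recompute_yield(merged)
    return merged


def smoothed_production(
    series: StatSeries, params: SmoothingParams = SmoothingParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Expected (climatological) production at every year in the span.

    Normalized convolution: at year t, Σ w(t,s)·prod(s) / Σ w(t,s) over
    observed years s, with Gaussian weights truncated at
    ``truncate × kernel_sd`` years.  A target year beyond truncation reach
    of every observation falls back to its nearest observation, so the
    estimate is defined (and positive where production is) on the whole
    span, including unobserved years.
    """
    obs = np.isfinite(series.production)
    if not obs.any():
        raise InvariantError(f"series {series.key}: no observed production")
    obs_years = series.years[obs].astype(float)
    obs_vals = series.production[obs]
    full_years = np.arange(series.years[0], series.years[-1] + 1)
    dist = full_years[:, None] - obs_years[None, :]
    w = np.exp(-0.5 * (dist / params.kernel_sd) ** 2)
    w[np.abs(dist) > params.truncate * params.kernel_sd] = 0.0
    totals = w.sum(axis=1)
    est = np.empty(len(full_years))
    reached = totals > 0
    est[reached] = (w[reached] @ obs_vals) / totals[reached]
    if not reached.all():
        nearest = np.abs(dist[~reached]).argmin(axis=1)
        est[~reached] = obs_vals[nearest]
    return full_years, est


def aggregate_admin(
    records: pd.DataFrame,
    unit_mapping: dict[str, str],
    coverage: CoverageParams = CoverageParams(),
    smoothing: SmoothingParams = SmoothingParams(),
    coarse_meta: dict[str, dict] | None = None,
    return_coverage: bool = False,
):
    """Aggregate fine-level records to coarser units behind the coverage gate.

    Parameters
    ----------
    records
        Fine-level records; every fnid present must appear in
        ``unit_mapping``.
    unit_mapping
        fine fnid -> coarse fnid (each fine unit has exactly one parent).
    coarse_meta
        Optional per-coarse-fnid metadata overrides, e.g.
        ``{"KE2010A101": {"admin_1": "Central", "admin_2": None}}``.
    return_coverage
        Also return the per (coarse unit, product, season, system, year)
        coverage diagnostics.

    For each output cell, coverage = Σ smoothed production of *reporting*
    members ÷ Σ smoothed production of *all* members (members that never
    report the product contribute to neither sum — there is nothing to
    expect of them).  Cells meeting the gate get the plain sum of reported
    values (never inflated by 1/coverage) and a recomputed yield; cells
    failing it are marked missing and omitted from the output table.
    """
    fine_fnids = set(records["fnid"].dropna())
    orphans = sorted(fine_fnids - set(unit_mapping))
    if orphans:
        raise InvariantError(f"fine unit(s) without coarse parent: {', '.join(orphans)}")

    work = records.copy()
    work["_coarse"] = work["fnid"].map(unit_mapping)
    out_rows: list[dict] = []
    coverage_rows: list[dict] = []

    group_cols = ["_coarse", "product", "season_name", "crop_production_system"]
    for (coarse, product, season, system), g in work.groupby(
        group_cols, dropna=False, sort=True
    ):
        members = {}
        for fnid, mg in g.groupby("fnid", sort=True):
            mg = mg.sort_values("harvest_year")
            if mg["production"].notna().any():
                series = StatSeries(
                    key=(fnid, product, season, system),
                    years=mg["harvest_year"].to_numpy(int),
                    production=mg["production"].to_numpy(float),
                    area=mg["area"].to_numpy(float),
                    yields=mg["yield"].to_numpy(float),
                )
                yrs, est = smoothed_production(series, smoothing)
                members[fnid] = (mg, dict(zip(yrs.tolist(), est.tolist())))
        if not members:
            continue

        all_years = sorted(
            set(
                int(y)
                for mg, _ in members.values()
                for y in mg.loc[mg["production"].notna(), "harvest_year"]
            )
        )
        for year in all_years:
            expected_total = 0.0
            expected_reporting = 0.0
            reporting_frames = []
            for fnid, (mg, clim) in members.items():
                yrs = list(clim)
                exp = clim.get(year, clim[min(yrs, key=lambda v: abs(v - year))])
                expected_total += exp
                rows = mg[(mg["harvest_year"] == year) & mg["production"].notna()]
                if len(rows):
                    expected_reporting += exp
                    reporting_frames.append(rows)
            cov = expected_reporting / expected_total if expected_total > 0 else 0.0
            coverage_rows.append(
                {
                    "fnid": coarse, "product": product, "season_name": season,
                    "crop_production_system": system, "harvest_year": year,
                    "coverage": cov, "n_reporting": len(reporting_frames),
                    "n_members": len(members),
                }
            )
            if cov + 1e-12 < coverage.min_coverage:
                continue  # observation marked missing: no output row
            rep = pd.concat(reporting_frames)
            template = rep.iloc[0]
            row = {c: template[c] for c in _GROUP_META}
            row["fnid"] = coarse
            row["product"] = product
            meta = (coarse_meta or {}).get(coarse, {})
            row.update(meta)
            row["qc_flag"] = FLAG_NONE
            row["production"] = rep["production"].sum(min_count=1)
            row["area"] = rep["area"].sum(min_count=1)
            out_rows.append(row)

    out = pd.DataFrame(out_rows, columns=CANONICAL_COLUMNS)
    if len(out):
        out["yield"] = _recompute_yield(out)
    cov_df = pd.DataFrame(
        coverage_rows,
        columns=[
            "fnid", "product", "season_name", "crop_production_system",
            "harvest_year", "coverage", "n_reporting", "n_members",
        ],
    )
    if return_coverage:
        return out, cov_df
    return out


def read_two_column_mapping(path, key: str | None = None, value: str | None = None) -> dict:
    """Load a two-column CSV mapping (e.g. sub-crop -> canonical crop)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: mapping needs two columns")
    k = key or df.columns[0]
    v = value or df.columns[1]
    return dict(zip(df[k], df[v]))
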