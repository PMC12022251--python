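"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure of subnational crop
reporting: per-district yield processes with trend and lognormal noise,
production consistent with area and yield, injected high-yield spikes and
repeated-value runs with known labels, boundary vintages realizing split /
merge / reorganization events with known classification, a cropland
surface, and a national reference series.  Geometries live on integer
planar grids so intersection areas are exact, and everything is
deterministic under a fixed seed (NumPy PCG64).

Clean backgrounds
-----------------
Recovery tests require that injected anomalies be the *only* rule
triggers, so background noise is rejection-sampled until it clears
explicit margins around both QC rules: every background Z-score below
2.5 (rule threshold 3), adjacent-year ratios below 2.0 (rule 2.5), and
every background second difference at least 1.3× outside the
1.5%-of-median band.  After injection the generator re-verifies, by the
same closed-form arithmetic, that the flag set implied by the rules
equals the injected truth, and redraws the series otherwise.  This makes
precision = recall = 1 a property of the fixture, not a tuning outcome;
unconstrained noise at any realistic level occasionally triggers either
rule by chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import InvariantError
from .io import zonal_cropland_area
from .model import CANONICAL_COLUMNS, AdminUnit, CroplandRaster
from .calibration import BoundaryChangeEvent

_Z_MARGIN = 2.5
_RATIO_MARGIN = 2.0
_BAND_MARGIN = 1.3
_MAX_REDRAWS = 500


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one synthetic study scenario.

    Yields are in t/ha, areas in ha, production in mt.  Defaults describe
    a small two-region country with 10 districts, 20 years of annual-season
    records for two crops, modest interannual variability (CV 0.12 — the
    low-variability end of subnational yield records, chosen so clean
    backgrounds are cheap to sample), two injected spikes and two injected
    repeated-value runs.
    """

    seed: int = 0
    country: str = "Synthetica"
    country_code: str = "SY"
    n_admin1: int = 2
    n_admin2: int = 5  # districts per region (grid columns)
    year_start: int = 2001
    n_years: int = 20
    crops: tuple[str, ...] = ("maize", "millet")
    season_name: str = "annual"
    crop_production_system: str = "none"
    planting_month: int = 3
    harvest_month: int = 11
    mean_yield: float = 1.5
    yield_trend: float = 0.01
    yield_cv: float = 0.12
    base_area: float = 5000.0
    area_cv: float = 0.05
    n_outliers: int = 2
    outlier_multiplier: float = 6.0
    n_repeat_runs: int = 2
    run_years: int = 5
    boundary_event: str | None = None  # "split" | "merge" | "reorganize"
    event_year: int | None = None
    split_ratio: tuple[float, float] = (0.4, 0.6)
    reporting_prob: float = 1.0
    clean_background: bool = True
    unit_size: float = 10.0
    cell_size: float = 1.0
    cropland_mean: float = 1.0  # ha per cell
    cropland_cv: float = 0.0
    cropland_zero_region: tuple[float, float, float, float] | None = None
    reference_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("reporting_prob",):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvariantError(f"{name} must be in [0, 1]")
        if self.boundary_event not in (None, "split", "merge", "reorganize"):
            raise InvariantError(f"unknown boundary_event '{self.boundary_event}'")
        if self.boundary_event == "merge" and self.n_admin2 < 2:
            raise InvariantError("merge event needs at least 2 districts")
        if self.boundary_event == "reorganize" and self.n_admin2 < 3:
            raise InvariantError("reorganize event needs at least 3 districts")
        if not math.isclose(sum(self.split_ratio), 1.0):
            raise InvariantError("split_ratio must sum to 1")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_start + self.n_years)

    @property
    def effective_event_year(self) -> int:
        return (
            self.event_year
            if self.event_year is not None
            else self.year_start + self.n_years // 2
        )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _district_fnid(config: ScenarioConfig, vintage_year: int, index: int) -> str:
    return f"{config.country_code}{vintage_year}A2{index:02d}"


def make_admin_vintages(
    config: ScenarioConfig,
) -> tuple[list[AdminUnit], list[AdminUnit], list[BoundaryChangeEvent]]:
    """Two boundary vintages plus the true change-event list.

    Districts are ``unit_size``-sided squares on an integer grid, one row
    of districts per region.  The configured event is realized in the
    first row; unchanged districts keep their fnid across vintages.
    """
    S = config.unit_size
    y0, yev = config.year_start, config.effective_event_year
    old: list[AdminUnit] = []
    for r in range(config.n_admin1):
        for c in range(config.n_admin2):
            idx = r * config.n_admin2 + c
            old.append(
                AdminUnit(
                    fnid=_district_fnid(config, y0, idx),
                    country_code=config.country_code,
                    level=2,
                    name=f"District {r}-{c}",
                    geometry=box(c * S, r * S, (c + 1) * S, (r + 1) * S),
                    vintage=str(y0),
                )
            )

    def with_vintage(u: AdminUnit) -> AdminUnit:
        return AdminUnit(u.fnid, u.country_code, u.level, u.name, u.geometry, str(yev))

    events: list[BoundaryChangeEvent] = []
    if config.boundary_event is None:
        return old, [with_vintage(u) for u in old], events

    if config.boundary_event == "split":
        target = old[0]
        halves = [box(0, 0, S / 2, S), box(S / 2, 0, S, S)]
        children = [
            AdminUnit(
                fnid=f"{_district_fnid(config, yev, 0)}{suffix}",
                country_code=config.country_code,
                level=2,
                name=f"{target.name}{suffix}",
                geometry=geom,
                vintage=str(yev),
            )
            for suffix, geom in zip(("a", "b"), halves)
        ]
        new = children + [with_vintage(u) for u in old[1:]]
        events.append(
            BoundaryChangeEvent([target], children, case="A", kind="split")
        )
    elif config.boundary_event == "merge":
        targets = old[:2]
        merged = AdminUnit(
            fnid=f"{_district_fnid(config, yev, 0)}m",
            country_code=config.country_code,
            level=2,
            name="District 0-0+1",
            geometry=box(0, 0, 2 * S, S),
            vintage=str(yev),
        )
        new = [merged] + [with_vintage(u) for u in old[2:]]
        events.append(
            BoundaryChangeEvent(targets, [merged], case="A", kind="merge")
        )
    else:  # reorganize: 3 districts re-tiled into 4 with shifted borders
        targets = old[:3]
        cuts = [0.0, 0.8 * S, 1.6 * S, 2.3 * S, 3.0 * S]
        newbies = [
            AdminUnit(
                fnid=f"{_district_fnid(config, yev, i)}r",
                country_code=config.country_code,
                level=2,
                name=f"District 0-new{i}",
                geometry=box(cuts[i], 0, cuts[i + 1], S),
                vintage=str(yev),
            )
            for i in range(4)
        ]
        new = newbies + [with_vintage(u) for u in old[3:]]
        events.append(
            BoundaryChangeEvent(targets, newbies, case="B", kind="reorganize")
        )
    return old, new, events


def make_cropland_raster(
    config: ScenarioConfig, units: list[AdminUnit] | None = None
) -> CroplandRaster:
    """Cropland surface covering the admin grid (ha per cell)."""
    rng = np.random.default_rng(config.seed + 7)
    if units is None:
        xmax = config.n_admin2 * config.unit_size
        ymax = config.n_admin1 * config.unit_size
        bounds = (0.0, 0.0, xmax, ymax)
    else:
        xs = [u.geometry.bounds for u in units]
        bounds = (
            min(b[0] for b in xs), min(b[1] for b in xs),
            max(b[2] for b in xs), max(b[3] for b in xs),
        )
    dx = dy = config.cell_size
    ncol = int(math.ceil((bounds[2] - bounds[0]) / dx))
    nrow = int(math.ceil((bounds[3] - bounds[1]) / dy))
    if config.cropland_cv > 0:
        sigma = math.sqrt(math.log(1 + config.cropland_cv**2))
        values = config.cropland_mean * rng.lognormal(
            -0.5 * sigma**2, sigma, size=(nrow, ncol)
        )
    else:
        values = np.full((nrow, ncol), config.cropland_mean)
    transform = (bounds[0], bounds[3], dx, dy)
    raster = CroplandRaster(values=values, transform=transform, crs=None)
    if config.cropland_zero_region is not None:
        x0, y0_, x1, y1 = config.cropland_zero_region
        for row in range(nrow):
            for col in range(ncol):
                cx0, cy0, cx1, cy1 = raster.cell_bounds(row, col)
                if cx0 >= x0 and cx1 <= x1 and cy0 >= y0_ and cy1 <= y1:
                    raster.values[row, col] = 0.0
    return raster


# ---------------------------------------------------------------------------
# Yield processes with guaranteed-clean backgrounds
# ---------------------------------------------------------------------------

def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1 + cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size=n)


def _background_is_clean(y: np.ndarray) -> bool:
    """Margin conditions ensuring neither QC rule can fire on background."""
    sd = y.std()
    if sd > 0 and np.max(np.abs(y - y.mean()) / sd) >= _Z_MARGIN:
        return False
    ratios = y[1:] / y[:-1]
    if np.max(np.maximum(ratios, 1 / ratios)) >= _RATIO_MARGIN:
        return False
    d = y[2:] - 2 * y[1:-1] + y[:-2]
    band = 0.015 * np.median(y)
    return bool(np.min(np.abs(d)) >= _BAND_MARGIN * band)


def _implied_flags(y: np.ndarray) -> np.ndarray:
    """Closed-form evaluation of both QC rules on a fully observed series
    (population sd, defaults); used to verify injected truth labels."""
    n = len(y)
    flags = np.zeros(n, dtype=int)
    d = y[2:] - 2 * y[1:-1] + y[:-2]
    band = 0.015 * np.median(y)
    small = np.abs(d) < band
    for start in range(len(d) - 2):
        if small[start : start + 3].all():
            flags[start : start + 5] = 2
    sd = y.std()
    if sd > 0 and y.max() > 0.5:
        z = (y - y.mean()) / sd
        for i in range(n):
            prev_ok = i > 0 and y[i] >= 2.5 * y[i - 1]
            next_ok = i < n - 1 and y[i] >= 2.5 * y[i + 1]
            if z[i] > 3 and (prev_ok or next_ok):
                flags[i] = 1
    return flags


def _draw_series(
    rng: np.random.Generator,
    config: ScenarioConfig,
    inject: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    """One yield series plus its truth-flag vector.

    ``inject`` is None, "spike", or "run".  Redraws until the background
    margins hold and (when injecting) the implied flag set equals the
    injected truth exactly.
    """
    n = config.n_years
    t = np.arange(n)
    base = config.mean_yield + config.yield_trend * t
    for _ in range(_MAX_REDRAWS):
        y = base * _lognormal_factors(rng, config.yield_cv, n)
        if config.clean_background and not _background_is_clean(y):
            continue
        truth = np.zeros(n, dtype=int)
        if inject == "spike":
            pos = int(rng.integers(2, n - 2))
            y = y.copy()
            y[pos] *= config.outlier_multiplier
            truth[pos] = 1
        elif inject == "run":
            start = int(rng.integers(1, n - config.run_years))
            y = y.copy()
            y[start : start + config.run_years] = y[start]
            truth[start : start + config.run_years] = 2
        if config.clean_background and not np.array_equal(_implied_flags(y), truth):
            continue
        return y, truth
    raise InvariantError(
        "could not sample a clean background; lower yield_cv or relax margins"
    )


def make_crop_series(
    config: ScenarioConfig,
    units: list[AdminUnit] | None = None,
    rng: np.random.Generator | None = None,
    no_inject_fnids: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crop records for the given units (default: the old vintage grid).

    Returns ``(records, truth)``: records in the canonical 16-column
    schema with qc_flag 0 and internally consistent yield = production /
    area; truth with one row per record carrying the injected
    ``true_flag``.  Injected series are always fully observed; other
    unit-years are observed with probability ``reporting_prob``.
    """
    if units is None:
        units, _, _ = make_admin_vintages(replace(config, boundary_event=None))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    series_keys = [(u, crop) for u in units for crop in config.crops]
    eligible = np.array(
        [
            i
            for i, (u, _) in enumerate(series_keys)
            if not no_inject_fnids or u.fnid not in no_inject_fnids
        ]
    )
    n_inject = config.n_outliers + config.n_repeat_runs
    if n_inject > len(eligible):
        raise InvariantError("more injections requested than series available")
    chosen = rng.choice(eligible, size=n_inject, replace=False)
    inject_kind = {int(i): "spike" for i in chosen[: config.n_outliers]}
    inject_kind.update({int(i): "run" for i in chosen[config.n_outliers :]})

    rows, truth_rows = [], []
    for s_idx, (unit, crop) in enumerate(series_keys):
        kind = inject_kind.get(s_idx)
        y, truth = _draw_series(rng, config, kind)
        area_base = config.base_area * rng.uniform(0.8, 1.2)
        area = area_base * _lognormal_factors(rng, config.area_cv, config.n_years)
        production = y * area
        observed = (
            np.ones(config.n_years, dtype=bool)
            if (kind is not None or config.reporting_prob >= 1)
            else rng.random(config.n_years) < config.reporting_prob
        )
        admin_1 = f"Region {unit.name.split(' ')[1].split('-')[0]}"
        for k, year in enumerate(config.years):
            if not observed[k]:
                continue
            rows.append(
                {
                    "fnid": unit.fnid,
                    "country": config.country,
                    "country_code": config.country_code,
                    "admin_1": admin_1,
                    "admin_2": unit.name,
                    "product": crop,
                    "season_name": config.season_name,
                    "planting_year": int(year),
                    "planting_month": config.planting_month,
                    "harvest_year": int(year),
                    "harvest_month": config.harvest_month,
                    "crop_production_system": config.crop_production_system,
                    "qc_flag": 0,
                    "area": float(area[k]),
                    "production": float(production[k]),
                    "yield": float(y[k]),
                }
            )
            truth_rows.append(
                {
                    "fnid": unit.fnid,
                    "product": crop,
                    "season_name": config.season_name,
                    "crop_production_system": config.crop_production_system,
                    "harvest_year": int(year),
                    "true_flag": int(truth[k]),
                }
            )
    records = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    truth_df = pd.DataFrame(truth_rows)
    return records, truth_df


# ---------------------------------------------------------------------------
# Full scenarios
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    """Everything one pipeline run needs, with ground truth attached."""

    config: ScenarioConfig
    old_units: list[AdminUnit]
    new_units: list[AdminUnit]
    truth_events: list[BoundaryChangeEvent]
    records: pd.DataFrame
    truth_flags: pd.DataFrame
    raster: CroplandRaster
    reference: pd.DataFrame
    truth_new_series: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rekey(df: pd.DataFrame, unit: AdminUnit, scale: float = 1.0) -> pd.DataFrame:
    out = df.copy()
    out["fnid"] = unit.fnid
    out["admin_2"] = unit.name
    if scale != 1.0:
        out["production"] = out["production"] * scale
        out["area"] = out["area"] * scale
    return out


def make_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Build a complete scenario: vintages, records split across vintages
    at the event year, cropland raster, truth labels, and a national
    reference series.

    For a split event the children's post-change statistics are exact
    proportional shares (``split_ratio``) of the parent process, so the
    Case A plan's recovered shares have a known ground truth.  For a
    reorganization the post-change series are the dasymetric transfer of
    the old processes under the true cropland weights.
    """
    rng = np.random.default_rng(config.seed)
    old_units, new_units, truth_events = make_admin_vintages(config)
    raster = make_cropland_raster(config, old_units)
    changed_fnids = {f for e in truth_events for f in e.old_fnids}
    base_records, truth = make_crop_series(
        config, units=old_units, rng=rng, no_inject_fnids=changed_fnids
    )
    yev = config.effective_event_year

    if not truth_events:
        records = base_records
        truth_flags = truth
        truth_new = pd.DataFrame()
    else:
        event = truth_events[0]
        changed = set(event.old_fnids)
        keep = base_records[~base_records["fnid"].isin(changed)]
        keep_truth = truth[~truth["fnid"].isin(changed)]
        affected = base_records[base_records["fnid"].isin(changed)]
        pre = affected[affected["harvest_year"] < yev]
        post = affected[affected["harvest_year"] >= yev]
        parts = [keep, pre]
        truth_parts = [keep_truth, truth[truth["fnid"].isin(changed)]]

        if event.kind == "split":
            for unit, ratio in zip(event.new_units, config.split_ratio):
                parts.append(_rekey(post, unit, scale=ratio))
        elif event.kind == "merge":
            merged_unit = event.new_units[0]
            key_cols = ["product", "season_name", "crop_production_system",
                        "harvest_year"]
            agg = {
                c: "first"
                for c in CANONICAL_COLUMNS
                if c not in key_cols + ["area", "production", "yield"]
            }
            agg.update({"area": "sum", "production": "sum"})
            summed = post.groupby(key_cols, dropna=False, sort=True, as_index=False).agg(agg)
            summed["yield"] = summed["production"] / summed["area"]
            parts.append(_rekey(summed[CANONICAL_COLUMNS], merged_unit))
        else:  # reorganize: dasymetric truth under the actual raster
            old_by = {u.fnid: u for u in event.old_units}
            old_cropland = {
                f: zonal_cropland_area(raster, u.geometry) for f, u in old_by.items()
            }
            for unit in event.new_units:
                pieces = []
                for of, ou in old_by.items():
                    g = unit.geometry.intersection(ou.geometry)
                    if g.is_empty or g.area <= 0:
                        continue
                    w = zonal_cropland_area(raster, g) / old_cropland[of]
                    sub = post[post["fnid"] == of]
                    pieces.append((w, sub))
                if not pieces:
                    continue
                key_cols = ["product", "season_name", "crop_production_system",
                            "harvest_year"]
                combined = None
                for w, sub in pieces:
                    scaled = sub.copy()
                    scaled["production"] *= w
                    scaled["area"] *= w
                    if combined is None:
                        combined = scaled
                    else:
                        merged = combined.merge(
                            scaled[key_cols + ["production", "area"]],
                            on=key_cols, how="inner", suffixes=("", "_b"),
                        )
                        merged["production"] += merged.pop("production_b")
                        merged["area"] += merged.pop("area_b")
                        combined = merged
                combined["yield"] = combined["production"] / combined["area"]
                parts.append(_rekey(combined[CANONICAL_COLUMNS], unit))
        records = pd.concat(parts, ignore_index=True)[CANONICAL_COLUMNS]
        # truth flags: injected labels apply to the pre-change rows that
        # remain; post-change derived rows are unlabelled background (0)
        derived = records.merge(
            pd.concat(truth_parts, ignore_index=True),
            on=["fnid", "product", "season_name", "crop_production_system",
                "harvest_year"],
            how="left",
        )
        truth_flags = derived[
            ["fnid", "product", "season_name", "crop_production_system",
             "harvest_year", "true_flag"]
        ].fillna({"true_flag": 0})
        truth_flags["true_flag"] = truth_flags["true_flag"].astype(int)
        truth_new = pd.DataFrame()

    reference = (
        records[records["production"].notna()]
        .groupby(["country_code", "product", "harvest_year"])["production"]
        .sum()
        .reset_index()
        .rename(columns={"harvest_year": "year"})
    )
    if config.reference_noise_cv > 0:
        factors = _lognormal_factors(rng, config.reference_noise_cv, len(reference))
        reference["production"] = reference["production"] * factors

    return SyntheticScenario(
        config=config,
        old_units=old_units,
        new_units=new_units,
        truth_events=truth_events,
        records=records,
        truth_flags=truth_flags,
        raster=raster,
        reference=reference,
    )
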