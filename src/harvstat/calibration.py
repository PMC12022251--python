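"""Calibration of crop statistics across administrative boundary changes.

When a country redraws its subnational units, statistics reported on the
old units must be re-expressed on the current units to give continuous
series.  Two regimes are distinguished:

* **Case A** — the outer boundary of the affected group is conserved and
  each new unit nests inside a single old unit (a pure split, or the
  degenerate inverse, a merge).  The old series is apportioned to the new
  units in proportion to their mean quantity produced observed after the
  change:  X_i = X_old · P_i / Σ_j P_j.  Because the same share scales
  production and area, the implied yield of every new unit equals the old
  unit's yield, and per-year totals are conserved exactly.  Shares are
  built per crop — districts differ in what they grow.

* **Case B** — boundaries genuinely moved, so post-change production
  shares of the new units say nothing about the old footprint.  Statistics
  transfer dasymetrically by cropland overlap:
  X_new = Σ_j X_j · A_new,j / A_j, where A_j is the cropland area of old
  unit j and A_new,j the cropland area of the old∩new intersection.  These
  weights are crop-independent.

Units whose area changes by less than ``area_change_threshold`` (default
10%) are passed through (relabelled at most); calibration is reserved for
substantive reorganizations.  A conservation report compares totals before
and after as a closing check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .errors import CRSMismatchError, InvariantError
from .io import zonal_cropland_area
from .model import AdminUnit, CroplandRaster

#: Fraction of the union area the symmetric difference may reach while the
#: outer boundary still counts as conserved (Case A test).
SYM_DIFF_TOL = 0.01

#: Minimum intersection area, as a fraction of the smaller unit, for two
#: units to count as geometrically related.
_INTERSECT_FRAC = 1e-9


@dataclass
class BoundaryChangeEvent:
    """One connected group of old units reorganized into new units."""

    old_units: list[AdminUnit]
    new_units: list[AdminUnit]
    case: str  # "A" or "B"
    kind: str  # "split" | "merge" | "rename" | "reorganize"
    area_changes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.old_units or not self.new_units:
            raise InvariantError("boundary event needs old and new units")

    @property
    def old_fnids(self) -> list[str]:
        return [u.fnid for u in self.old_units]

    @property
    def new_fnids(self) -> list[str]:
        return [u.fnid for u in self.new_units]


@dataclass
class CalibrationPlan:
    """Ratios mapping old-unit series onto new units.

    Case A: ``shares[crop][new_fnid]`` with Σ_i shares = 1 per crop, plus
    ``default_shares`` for crops never observed post-change.
    Case B: ``weights[new_fnid][old_fnid]`` = cropland(new∩old)/cropland(old).
    ``provenance`` records how each ratio was obtained.
    """

    event: BoundaryChangeEvent
    case: str
    shares: dict[str, dict[str, float]] = field(default_factory=dict)
    default_shares: dict[str, float] = field(default_factory=dict)
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_boundary_changes(
    old_vintage: list[AdminUnit],
    new_vintage: list[AdminUnit],
    area_change_threshold: float = 0.10,
    sym_diff_tol: float = SYM_DIFF_TOL,
) -> list[BoundaryChangeEvent]:
    """Find and classify boundary changes between two vintages.

    Old and new units whose geometries essentially coincide (mutual best
    intersection, area change below the threshold relative to the old
    area) are stable 1:1 matches and produce no event.  Remaining units
    are grouped into connected components of the intersection graph and
    each component is classified Case A (conserved outer boundary and pure
    split or pure merge) or Case B (everything else).
    """
    if not old_vintage or not new_vintage:
        raise InvariantError("both vintages must be non-empty")
    crss = {u.crs for u in old_vintage} | {u.crs for u in new_vintage}
    if len(crss) > 1:
        raise CRSMismatchError(f"vintages mix coordinate references: {crss}")

    inter = {}
    for o in old_vintage:
        for n in new_vintage:
            a = o.geometry.intersection(n.geometry).area
            if a > _INTERSECT_FRAC * min(o.geometry.area, n.geometry.area):
                inter[(o.fnid, n.fnid)] = a

    old_by, new_by = {u.fnid: u for u in old_vintage}, {u.fnid: u for u in new_vintage}
    best_new = {}
    for o in old_vintage:
        cands = {n: a for (of, n), a in inter.items() if of == o.fnid}
        if cands:
            best_new[o.fnid] = max(cands, key=cands.get)
    best_old = {}
    for n in new_vintage:
        cands = {of: a for (of, nf), a in inter.items() if nf == n.fnid}
        if cands:
            best_old[n.fnid] = max(cands, key=cands.get)

    stable: dict[str, str] = {}
    for of, nf in best_new.items():
        if best_old.get(nf) != of:
            continue
        a_old = old_by[of].geometry.area
        a_new = new_by[nf].geometry.area
        change = abs(a_new - a_old) / a_old
        if change < area_change_threshold and inter[(of, nf)] >= (
            1 - area_change_threshold
        ) * a_old:
            stable[of] = nf

    rest_old = [u for u in old_vintage if u.fnid not in stable]
    rest_new = [u for u in new_vintage if u.fnid not in set(stable.values())]

    # connected components of the old/new intersection graph (union-find)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for u in rest_old:
        parent[("O", u.fnid).__str__()] = str(("O", u.fnid))
    for u in rest_new:
        parent[str(("N", u.fnid))] = str(("N", u.fnid))
    for u in rest_old:
        for v in rest_new:
            if (u.fnid, v.fnid) in inter:
                union(str(("O", u.fnid)), str(("N", v.fnid)))

    components: dict[str, dict[str, list[AdminUnit]]] = {}
    for u in rest_old:
        root = find(str(("O", u.fnid)))
        components.setdefault(root, {"old": [], "new": []})["old"].append(u)
    for u in rest_new:
        root = find(str(("N", u.fnid)))
        components.setdefault(root, {"old": [], "new": []})["new"].append(u)

    events: list[BoundaryChangeEvent] = []
    for comp in components.values():
        olds, news = comp["old"], comp["new"]
        if not olds or not news:
            lost = [u.fnid for u in olds + news]
            warnings.warn(
                f"unit(s) {lost} have no counterpart in the other vintage; skipped"
            )
            continue
        events.append(_classify(olds, news, inter, sym_diff_tol, old_by, new_by))
    return events


def _classify(olds, news, inter, sym_diff_tol, old_by, new_by) -> BoundaryChangeEvent:
    union_old = unary_union([u.geometry for u in olds])
    union_new = unary_union([u.geometry for u in news])
    union_all = union_old.union(union_new)
    outer_conserved = (
        union_old.symmetric_difference(union_new).area <= sym_diff_tol * union_all.area
    )
    tol = 1 - sym_diff_tol

    def nested_within_single(units, others):
        for u in units:
            overlaps = [
                inter.get((u.fnid, o.fnid)) or inter.get((o.fnid, u.fnid)) or 0.0
                for o in others
            ]
            if max(overlaps) < tol * u.geometry.area:
                return False
        return True

    pure_split = nested_within_single(news, olds)
    pure_merge = nested_within_single(olds, news)

    area_changes = {}
    for o in olds:
        matches = [
            new_by[nf].geometry.area for (of, nf) in inter if of == o.fnid
        ]
        if matches:
            best = max(
                (nf for (of, nf) in inter if of == o.fnid),
                key=lambda nf: inter[(o.fnid, nf)],
            )
            area_changes[o.fnid] = (
                abs(new_by[best].geometry.area - o.geometry.area) / o.geometry.area
            )

    if outer_conserved and (pure_split or pure_merge):
        case = "A"
        if len(olds) == 1 and len(news) == 1:
            kind = "rename"
        elif pure_split and len(news) > len(olds):
            kind = "split"
        elif pure_merge and len(news) < len(olds):
            kind = "merge"
        else:
            kind = "split" if pure_split else "merge"
    else:
        case, kind = "B", "reorganize"
    return BoundaryChangeEvent(
        old_units=olds, new_units=news, case=case, kind=kind, area_changes=area_changes
    )


# ---------------------------------------------------------------------------
# Case A
# ---------------------------------------------------------------------------

def _annual_production_by_unit(records: pd.DataFrame, fnids: list[str], crop: str):
    """Per-unit annual production totals (summed over seasons/systems)."""
    sub = records[(records["fnid"].isin(fnids)) & (records["product"] == crop)]
    sub = sub[sub["production"].notna()]
    return {
        fnid: g.groupby("harvest_year")["production"].sum()
        for fnid, g in sub.groupby("fnid")
    }


def _geometric_shares(
    event: BoundaryChangeEvent, raster: CroplandRaster | None
) -> tuple[dict[str, float], str]:
    """Fallback shares from cropland (preferred) or plain polygon area."""
    if raster is not None:
        vals = {
            u.fnid: zonal_cropland_area(raster, u.geometry) for u in event.new_units
        }
        how = "cropland-area shares"
        if sum(vals.values()) <= 0:
            vals = {u.fnid: u.geometry.area for u in event.new_units}
            how = "polygon-area shares (zero cropland)"
    else:
        vals = {u.fnid: u.geometry.area for u in event.new_units}
        how = "polygon-area shares (no cropland raster)"
    total = sum(vals.values())
    return {f: v / total for f, v in vals.items()}, how


def build_case_a_plan(
    event: BoundaryChangeEvent,
    new_records: pd.DataFrame,
    raster: CroplandRaster | None = None,
) -> CalibrationPlan:
    """Build per-crop apportionment shares from post-change production means.

    For each crop reported by the new units, P_i is the mean annual
    production of new unit i over post-change years; when the units'
    reporting windows differ, means are taken over the common years when
    any exist (comparability), else per-unit with a warning.  Crops for
    which some new unit never reports fall back to cropland-area shares
    (or polygon-area shares without a raster), recorded in provenance.
    """
    if event.case != "A":
        raise InvariantError("build_case_a_plan requires a Case A event")
    plan = CalibrationPlan(event=event, case="A")
    if event.kind == "merge":
        plan.provenance.append("merge: new series is the sum of old series")
        return plan

    default, how = _geometric_shares(event, raster)
    plan.default_shares = default

    crops = sorted(new_records.loc[new_records["fnid"].isin(event.new_fnids), "product"].dropna().unique())
    for crop in crops:
        per_unit = _annual_production_by_unit(new_records, event.new_fnids, crop)
        if set(per_unit) != set(event.new_fnids) or any(
            s.sum() <= 0 for s in per_unit.values()
        ):
            plan.shares[crop] = dict(default)
            plan.provenance.append(
                f"{crop}: incomplete/zero post-change reporting; fallback to {how}"
            )
            warnings.warn(f"case A {crop}: falling back to {how}")
            continue
        common = set.intersection(*(set(s.index) for s in per_unit.values()))
        if common:
            means = {f: float(s.loc[sorted(common)].mean()) for f, s in per_unit.items()}
            plan.provenance.append(
                f"{crop}: means over {len(common)} common post-change year(s)"
            )
        else:
            means = {f: float(s.mean()) for f, s in per_unit.items()}
            plan.provenance.append(f"{crop}: per-unit means (no common years)")
            warnings.warn(f"case A {crop}: no common reporting years across new units")
        total = sum(means.values())
        if total <= 0:
            plan.shares[crop] = dict(default)
            plan.provenance.append(f"{crop}: all-zero means; fallback to {how}")
        else:
            plan.shares[crop] = {f: m / total for f, m in means.items()}
    return plan


def _new_unit_meta(unit: AdminUnit, template: pd.Series) -> dict:
    meta = {"fnid": unit.fnid}
    if unit.level == 1:
        meta["admin_1"] = unit.name
        meta["admin_2"] = np.nan
    else:
        meta["admin_2"] = unit.name
    return meta


def apply_case_a(plan: CalibrationPlan, old_records: pd.DataFrame) -> pd.DataFrame:
    """Apportion old-unit records onto the new units (or sum, for a merge).

    Production and area scale by the same share, so yield carries over
    unchanged; a missing old value propagates to every new unit.  QC flags
    carry over under a split (all three rule statistics are invariant
    under positive rescaling); a merge mixes series, so flags reset to 0.
    """
    if plan.case != "A":
        raise InvariantError("apply_case_a requires a Case A plan")
    event = plan.event
    rows = old_records[old_records["fnid"].isin(event.old_fnids)]
    if event.kind == "merge":
        return _combine_contributors(
            rows, event, {event.new_fnids[0]: {f: 1.0 for f in event.old_fnids}}
        )
    out = []
    for _, row in rows.iterrows():
        crop = row["product"]
        shares = plan.shares.get(crop, plan.default_shares)
        if not shares:
            shares = {u.fnid: 1.0 / len(event.new_units) for u in event.new_units}
        for unit in event.new_units:
            s = shares[unit.fnid]
            new = row.copy()
            for k, v in _new_unit_meta(unit, row).items():
                new[k] = v
            new["production"] = row["production"] * s
            new["area"] = row["area"] * s
            # yield = (s·P)/(s·A) = P/A: unchanged by construction
            out.append(new)
    return pd.DataFrame(out).reset_index(drop=True)[old_records.columns]


# ---------------------------------------------------------------------------
# Case B
# ---------------------------------------------------------------------------

def build_case_b_plan(
    event: BoundaryChangeEvent, raster: CroplandRaster
) -> CalibrationPlan:
    """Dasymetric weights w = cropland(new∩old_j) / cropland(old_j).

    Weights are crop-independent and lie in [0, 1]; an old unit with zero
    cropland falls back to plain polygon-area ratios with a warning.
    """
    plan = CalibrationPlan(event=event, case="B")
    old_cropland = {}
    for o in event.old_units:
        a = zonal_cropland_area(raster, o.geometry)
        old_cropland[o.fnid] = a
        if a <= 0:
            warnings.warn(
                f"old unit {o.fnid} has zero cropland; using polygon-area ratios"
            )
    for n in event.new_units:
        plan.weights[n.fnid] = {}
        for o in event.old_units:
            g = n.geometry.intersection(o.geometry)
            if g.is_empty or g.area <= _INTERSECT_FRAC * o.geometry.area:
                continue  # disjoint pair: weight 0, dropped
            if old_cropland[o.fnid] > 0:
                w = zonal_cropland_area(raster, g) / old_cropland[o.fnid]
                plan.provenance.append(f"{n.fnid}<-{o.fnid}: cropland ratio {w:.6f}")
            else:
                w = g.area / o.geometry.area
                plan.provenance.append(f"{n.fnid}<-{o.fnid}: polygon-area ratio {w:.6f}")
            plan.weights[n.fnid][o.fnid] = float(min(max(w, 0.0), 1.0))
    return plan


def _combine_contributors(
    old_rows: pd.DataFrame,
    event: BoundaryChangeEvent,
    weights: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Weighted combination Σ_j w_j X_j per new unit; a contributor that is
    missing in a year makes the output year missing (partial sums would
    silently underestimate)."""
    new_by = {u.fnid: u for u in event.new_units}
    out_rows = []
    key_cols = ["product", "season_name", "crop_production_system", "harvest_year"]
    for new_fnid, w in weights.items():
        contributors = {f: wf for f, wf in w.items() if wf > 0}
        if not contributors:
            continue
        sub = old_rows[old_rows["fnid"].isin(contributors)]
        # contributors that report this (product, season, system) at all
        for key, g in sub.groupby(key_cols[:-1], dropna=False, sort=True):
            active = {
                f: contributors[f] for f in g["fnid"].unique() if f in contributors
            }
            years = sorted(g["harvest_year"].unique())
            for year in years:
                gy = g[g["harvest_year"] == year]
                present = set(gy["fnid"])
                template = gy.iloc[0]
                row = template.copy()
                for k, v in _new_unit_meta(new_by[new_fnid], template).items():
                    row[k] = v
                row["qc_flag"] = 0
                for stat in ("production", "area"):
                    if present != set(active) or gy[stat].isna().any():
                        row[stat] = np.nan
                    else:
                        vals = {f: float(v) for f, v in zip(gy["fnid"], gy[stat])}
                        row[stat] = sum(active[f] * vals[f] for f in active)
                if (
                    pd.notna(row["area"]) and row["area"] > 0 and pd.notna(row["production"])
                ):
                    row["yield"] = row["production"] / row["area"]
                else:
                    row["yield"] = np.nan
                out_rows.append(row)
    if not out_rows:
        return old_rows.iloc[0:0].copy()
    return pd.DataFrame(out_rows).reset_index(drop=True)[old_rows.columns]


def apply_case_b(plan: CalibrationPlan, old_records: pd.DataFrame) -> pd.DataFrame:
    """Transfer old series onto new units with the dasymetric weights."""
    if plan.case != "B":
        raise InvariantError("apply_case_b requires a Case B plan")
    rows = old_records[old_records["fnid"].isin(plan.event.old_fnids)]
    return _combine_contributors(rows, plan.event, plan.weights)


# ---------------------------------------------------------------------------
# Conservation check and orchestration
# ---------------------------------------------------------------------------

def verify_conservation(
    before: pd.DataFrame, after: pd.DataFrame, plan: CalibrationPlan
) -> pd.DataFrame:
    """Compare per-year, per-crop totals over the event footprint.

    Case A conserves exactly (shares sum to 1).  Case B conserves iff the
    new units tile each old unit's cropland (Σ_new w = 1 per old unit);
    the report carries the per-old-unit tiling sums so a defect can be
    traced to untiled cropland.
    """
    old_f, new_f = plan.event.old_fnids, plan.event.new_fnids
    b = before[before["fnid"].isin(old_f)]
    a = after[after["fnid"].isin(new_f)]
    tiling = {
        of: sum(plan.weights[nf].get(of, 0.0) for nf in plan.weights)
        for of in old_f
    } if plan.case == "B" else {of: 1.0 for of in old_f}
    rows = []
    keys = ["product", "harvest_year"]
    tb = b.groupby(keys, dropna=False)[["production", "area"]].sum(min_count=1)
    ta = a.groupby(keys, dropna=False)[["production", "area"]].sum(min_count=1)
    for key in sorted(set(tb.index) | set(ta.index)):
        row = {"product": key[0], "harvest_year": key[1]}
        for stat in ("production", "area"):
            vb = tb[stat].get(key, np.nan)
            va = ta[stat].get(key, np.nan)
            row[f"{stat}_before"] = vb
            row[f"{stat}_after"] = va
            if pd.notna(vb) and vb != 0 and pd.notna(va):
                row[f"{stat}_rel_discrepancy"] = (va - vb) / vb
            else:
                row[f"{stat}_rel_discrepancy"] = np.nan
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["tiling_sums"] = tiling
    report.attrs["tiling_holds"] = all(
        abs(1 - t) <= 1e-9 for t in tiling.values()
    )
    return report


def calibrate(
    records: pd.DataFrame,
    old_vintage: list[AdminUnit],
    new_vintage: list[AdminUnit],
    raster: CroplandRaster | None = None,
    area_change_threshold: float = 0.10,
):
    """End-to-end calibration of a records table onto the new vintage.

    Records on stable old fnids are relabelled (statistics untouched);
    records on event old units are transformed by the applicable Case A/B
    plan; records already on new-vintage fnids pass through.  Returns
    ``(calibrated, events, plans, conservation_reports)``.
    """
    events = detect_boundary_changes(
        old_vintage, new_vintage, area_change_threshold=area_change_threshold
    )
    old_by = {u.fnid: u for u in old_vintage}
    new_by = {u.fnid: u for u in new_vintage}
    event_old = {f for e in events for f in e.old_fnids}

    stable_map = {}
    for of, old_unit in old_by.items():
        if of in event_old:
            continue
        if of in new_by:
            stable_map[of] = of
        else:
            cands = [
                n for n in new_vintage
                if n.geometry.intersection(old_unit.geometry).area
                > (1 - area_change_threshold) * old_unit.geometry.area
            ]
            if cands:
                stable_map[of] = cands[0].fnid

    untouched = records[~records["fnid"].isin(event_old)].copy()
    relabel = untouched["fnid"].map(lambda f: stable_map.get(f, f))
    renamed = relabel != untouched["fnid"]
    if renamed.any():
        for idx in untouched.index[renamed]:
            unit = new_by[relabel[idx]]
            for k, v in _new_unit_meta(unit, untouched.loc[idx]).items():
                untouched.loc[idx, k] = v
    parts = [untouched]

    plans, reports = [], []
    for event in events:
        old_rows = records[records["fnid"].isin(event.old_fnids)]
        if event.case == "A":
            new_rows_existing = records[records["fnid"].isin(event.new_fnids)]
            plan = build_case_a_plan(event, new_rows_existing, raster=raster)
            calibrated = apply_case_a(plan, old_rows)
        else:
            if raster is None:
                raise InvariantError(
                    f"case B event {event.old_fnids} requires a cropland raster"
                )
            plan = build_case_b_plan(event, raster)
            calibrated = apply_case_b(plan, old_rows)
        plans.append(plan)
        reports.append(verify_conservation(records, calibrated, plan))
        parts.append(calibrated)

    out = pd.concat(parts, ignore_index=True)
    return out, events, plans, reports
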