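"""Boundary-change detection, Case A/B calibration, conservation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from harvstat.calibration import (
    BoundaryChangeEvent,
    apply_case_a,
    apply_case_b,
    build_case_a_plan,
    build_case_b_plan,
    calibrate,
    detect_boundary_changes,
    verify_conservation,
)
from harvstat.model import CANONICAL_COLUMNS, AdminUnit, CroplandRaster


def _unit(fnid, geom, name=None, level=2):
    return AdminUnit(fnid, "SY", level, name or fnid, geom, "2000")


def _records(entries):
    base = {
        "fnid": "OLD", "country": "Synthetica", "country_code": "SY",
        "admin_1": "Region 0", "admin_2": "Old", "product": "maize",
        "season_name": "annual", "planting_year": 2000, "planting_month": 3,
        "harvest_year": 2000, "harvest_month": 11,
        "crop_production_system": "none", "qc_flag": 0,
        "area": np.nan, "production": np.nan, "yield": np.nan,
    }
    rows = []
    for e in entries:
        row = dict(base)
        row.update(e)
        row.setdefault("planting_year", row["harvest_year"])
        rows.append(row)
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


class TestDetection:
    def test_identical_vintages_no_events(self):
        old = [_unit(f"U{i}", box(i, 0, i + 1, 1)) for i in range(3)]
        assert detect_boundary_changes(old, old) == []

    def test_small_area_change_passes_through(self):
        old = [_unit("U0", box(0, 0, 10, 10))]
        new = [_unit("V0", box(0, 0, 10.4, 10))]  # 4% growth < 10%
        assert detect_boundary_changes(old, new) == []

    def test_split_into_tiling_rectangles_is_case_a(self):
        old = [_unit("E1", box(0, 0, 10, 10))]
        new = [_unit("E1a", box(0, 0, 5, 10)), _unit("E1b", box(5, 0, 10, 10))]
        events = detect_boundary_changes(old, new)
        assert len(events) == 1
        assert (events[0].case, events[0].kind) == ("A", "split")
        assert set(events[0].new_fnids) == {"E1a", "E1b"}

    def test_merge_with_conserved_outer_boundary_is_case_a(self):
        old = [_unit("F1", box(0, 0, 5, 10)), _unit("F2", box(5, 0, 10, 10))]
        new = [_unit("G", box(0, 0, 10, 10))]
        events = detect_boundary_changes(old, new)
        assert (events[0].case, events[0].kind) == ("A", "merge")

    def test_reorganization_with_shifted_borders_is_case_b(self):
        old = [_unit(f"F{i}", box(10 * i, 0, 10 * (i + 1), 10)) for i in range(3)]
        cuts = [0, 8, 16, 23, 30]
        new = [_unit(f"G{i}", box(cuts[i], 0, cuts[i + 1], 10)) for i in range(4)]
        events = detect_boundary_changes(old, new)
        assert len(events) == 1
        assert events[0].case == "B"
        assert len(events[0].old_units) == 3 and len(events[0].new_units) == 4

    def test_detector_on_constructed_scenarios(self, split_scenario, reorganize_scenario):
        for sc in (split_scenario, reorganize_scenario):
            truth = sc.truth_events[0]
            events = detect_boundary_changes(sc.old_units, sc.new_units)
            assert len(events) == 1
            assert events[0].case == truth.case
            assert set(events[0].old_fnids) == set(truth.old_fnids)
            assert set(events[0].new_fnids) == set(truth.new_fnids)


class TestCaseA:
    def _event(self):
        return BoundaryChangeEvent(
            [_unit("E1", box(0, 0, 10, 10))],
            [_unit("E1a", box(0, 0, 5, 10)), _unit("E1b", box(5, 0, 10, 10))],
            case="A", kind="split",
        )

    def _post_split_records(self, p1=30.0, p2=90.0):
        rows = []
        for year in (2010, 2011):
            rows.append({"fnid": "E1a", "harvest_year": year, "production": p1})
            rows.append({"fnid": "E1b", "harvest_year": year, "production": p2})
        return _records(rows)

    def test_shares_from_post_split_means(self):
        plan = build_case_a_plan(self._event(), self._post_split_records())
        assert plan.shares["maize"]["E1a"] == pytest.approx(0.25)
        assert plan.shares["maize"]["E1b"] == pytest.approx(0.75)
        assert sum(plan.shares["maize"].values()) == pytest.approx(1.0)

    def test_equal_means_give_equal_shares(self):
        plan = build_case_a_plan(self._event(), self._post_split_records(50, 50))
        assert plan.shares["maize"]["E1a"] == pytest.approx(0.5)

    def test_apply_scales_both_statistics_and_preserves_yield(self):
        plan = build_case_a_plan(self._event(), self._post_split_records())
        old = _records([
            {"fnid": "E1", "harvest_year": 2000, "production": 100.0,
             "area": 50.0, "yield": 2.0},
            {"fnid": "E1", "harvest_year": 2001, "production": 120.0,
             "area": 50.0, "yield": 2.4},
        ])
        out = apply_case_a(plan, old)
        a = out[out["fnid"] == "E1a"].sort_values("harvest_year")
        b = out[out["fnid"] == "E1b"].sort_values("harvest_year")
        assert list(a["production"]) == pytest.approx([25.0, 30.0])
        assert list(b["production"]) == pytest.approx([75.0, 90.0])
        # same share scales area, so yield is untouched in every new unit
        for part in (a, b):
            assert list(part["production"] / part["area"]) == pytest.approx([2.0, 2.4])
        # per-year conservation
        report = verify_conservation(old, out, plan)
        assert np.allclose(report["production_rel_discrepancy"], 0.0, atol=1e-9)
        assert np.allclose(report["area_rel_discrepancy"], 0.0, atol=1e-9)

    def test_single_new_unit_rename_is_identity(self):
        event = BoundaryChangeEvent(
            [_unit("E1", box(0, 0, 10, 10))],
            [_unit("E1X", box(0, 0, 10, 10))],
            case="A", kind="rename",
        )
        plan = build_case_a_plan(
            event, _records([{"fnid": "E1X", "harvest_year": 2010, "production": 5.0}])
        )
        assert plan.shares["maize"]["E1X"] == pytest.approx(1.0)
        old = _records([{"fnid": "E1", "harvest_year": 2000, "production": 42.0,
                         "area": 10.0, "yield": 4.2}])
        out = apply_case_a(plan, old)
        assert out.iloc[0]["production"] == pytest.approx(42.0)

    def test_missing_old_year_propagates_to_all_new_units(self):
        plan = build_case_a_plan(self._event(), self._post_split_records())
        old = _records([
            {"fnid": "E1", "harvest_year": 2000},  # all statistics missing
        ])
        out = apply_case_a(plan, old)
        assert out["production"].isna().all() and len(out) == 2

    def test_unreported_crop_falls_back_to_geometric_shares(self):
        raster = CroplandRaster(np.ones((10, 10)), (0.0, 10.0, 1.0, 1.0))
        with pytest.warns(UserWarning, match="falling back"):
            plan = build_case_a_plan(
                self._event(),
                _records([{"fnid": "E1a", "harvest_year": 2010, "production": 3.0}]),
                raster=raster,
            )
        # E1b never reports maize: cropland shares are 50/50 on this raster
        assert plan.shares["maize"]["E1a"] == pytest.approx(0.5)


class TestCaseB:
    def _event(self):
        old = [_unit("F1", box(0, 0, 10, 10)), _unit("F2", box(10, 0, 20, 10))]
        new = [_unit("G", box(2, 0, 14, 10))]
        return BoundaryChangeEvent(old, new, case="B", kind="reorganize")

    def test_weights_are_cropland_overlap_ratios(self):
        raster = CroplandRaster(np.ones((10, 20)), (0.0, 10.0, 1.0, 1.0))
        plan = build_case_b_plan(self._event(), raster)
        assert plan.weights["G"]["F1"] == pytest.approx(0.8)  # 80 of 100 ha
        assert plan.weights["G"]["F2"] == pytest.approx(0.4)

    def test_weighted_transfer_arithmetic(self):
        event = self._event()
        plan = build_case_b_plan(
            event, CroplandRaster(np.ones((10, 20)), (0.0, 10.0, 1.0, 1.0))
        )
        plan.weights["G"] = {"F1": 0.4, "F2": 0.2}
        old = _records([
            {"fnid": "F1", "harvest_year": 2000, "production": 50.0, "area": 20.0,
             "yield": 2.5},
            {"fnid": "F2", "harvest_year": 2000, "production": 30.0, "area": 10.0,
             "yield": 3.0},
        ])
        out = apply_case_b(plan, old)
        assert out.iloc[0]["production"] == pytest.approx(50 * 0.4 + 30 * 0.2)  # 26
        assert out.iloc[0]["area"] == pytest.approx(20 * 0.4 + 10 * 0.2)
        assert out.iloc[0]["yield"] == pytest.approx(26.0 / 10.0)

    def test_identity_when_new_equals_old(self):
        old = [_unit("F1", box(0, 0, 10, 10))]
        new = [_unit("G", box(0, 0, 10, 10))]
        event = BoundaryChangeEvent(old, new, case="B", kind="reorganize")
        raster = CroplandRaster(np.ones((10, 10)), (0.0, 10.0, 1.0, 1.0))
        plan = build_case_b_plan(event, raster)
        assert plan.weights["G"]["F1"] == pytest.approx(1.0)
        oldrec = _records([{"fnid": "F1", "harvest_year": 2000, "production": 9.0,
                            "area": 3.0, "yield": 3.0}])
        out = apply_case_b(plan, oldrec)
        assert out.iloc[0]["production"] == pytest.approx(9.0)

    def test_missing_contributor_year_makes_output_missing(self):
        plan = build_case_b_plan(
            self._event(), CroplandRaster(np.ones((10, 20)), (0.0, 10.0, 1.0, 1.0))
        )
        old = _records([
            {"fnid": "F1", "harvest_year": 2000, "production": 50.0},
            {"fnid": "F2", "harvest_year": 2000, "production": 30.0},
            {"fnid": "F1", "harvest_year": 2001, "production": 55.0},
            # F2 does not report 2001
        ])
        out = apply_case_b(plan, old).set_index("harvest_year")
        assert np.isfinite(out.loc[2000, "production"])
        assert np.isnan(out.loc[2001, "production"])

    def test_conservation_under_exact_tiling_and_sliver_defect(self):
        old = [_unit("F1", box(0, 0, 10, 10)), _unit("F2", box(10, 0, 20, 10))]
        raster = CroplandRaster(np.ones((10, 20)), (0.0, 10.0, 1.0, 1.0))
        oldrec = _records([
            {"fnid": "F1", "harvest_year": 2000, "production": 50.0, "area": 20.0,
             "yield": 2.5},
            {"fnid": "F2", "harvest_year": 2000, "production": 30.0, "area": 10.0,
             "yield": 3.0},
        ])
        # exact tiling: two new units covering the full footprint
        new = [_unit("G1", box(0, 0, 12, 10)), _unit("G2", box(12, 0, 20, 10))]
        event = BoundaryChangeEvent(old, new, case="B", kind="reorganize")
        plan = build_case_b_plan(event, raster)
        out = apply_case_b(plan, oldrec)
        report = verify_conservation(oldrec, out, plan)
        assert report.attrs["tiling_holds"]
        assert np.allclose(report["production_rel_discrepancy"], 0.0, atol=1e-12)

        # dropped sliver: 10% of F2's cropland is not covered by any new unit
        new2 = [_unit("G1", box(0, 0, 12, 10)), _unit("G2", box(12, 0, 18, 10))]
        event2 = BoundaryChangeEvent(old, new2, case="B", kind="reorganize")
        plan2 = build_case_b_plan(event2, raster)
        out2 = apply_case_b(plan2, oldrec)
        report2 = verify_conservation(oldrec, out2, plan2)
        assert not report2.attrs["tiling_holds"]
        untiled_weight = 1.0 - sum(
            plan2.weights[g].get("F2", 0.0) for g in plan2.weights
        )
        expected_loss = untiled_weight * 30.0  # closed form: w_lost x P_old
        got = report2.set_index(["product", "harvest_year"])
        loss = (
            got.loc[("maize", 2000), "production_before"]
            - got.loc[("maize", 2000), "production_after"]
        )
        assert loss == pytest.approx(expected_loss, rel=1e-9)


class TestEndToEnd:
    def test_identity_vintages_are_a_noop(self, plain_scenario):
        sc = plain_scenario
        out, events, plans, reports = calibrate(
            sc.records, sc.old_units, sc.new_units, raster=sc.raster
        )
        assert events == []
        pd.testing.assert_frame_equal(
            out.sort_values(["fnid", "product", "harvest_year"]).reset_index(drop=True),
            sc.records.sort_values(["fnid", "product", "harvest_year"]).reset_index(drop=True),
        )

    def test_split_scenario_recovers_proportional_truth(self, split_scenario):
        sc = split_scenario
        out, events, plans, reports = calibrate(
            sc.records, sc.old_units, sc.new_units, raster=sc.raster
        )
        truth = sc.truth_events[0]
        ratios = dict(zip([u.fnid for u in truth.new_units], sc.config.split_ratio))
        for crop, shares in plans[0].shares.items():
            for fnid, share in shares.items():
                assert share == pytest.approx(ratios[fnid], rel=1e-12)
        # calibrated pre-split child series equal ratio x parent exactly
        old_fnid = truth.old_fnids[0]
        parent = sc.records[sc.records["fnid"] == old_fnid]
        for fnid, ratio in ratios.items():
            child = out[out["fnid"] == fnid].merge(
                parent, on=["product", "harvest_year"], suffixes=("", "_parent")
            )
            pre = child[child["harvest_year"] < sc.config.effective_event_year]
            assert len(pre)
            assert np.allclose(pre["production"], ratio * pre["production_parent"])
        for report in reports:
            assert np.allclose(
                report["production_rel_discrepancy"].dropna(), 0.0, atol=1e-9
            )

    def test_reorganize_scenario_conserves_under_full_tiling(self, reorganize_scenario):
        sc = reorganize_scenario
        out, events, plans, reports = calibrate(
            sc.records, sc.old_units, sc.new_units, raster=sc.raster
        )
        assert events[0].case == "B"
        assert reports[0].attrs["tiling_holds"]
        assert np.allclose(
            reports[0]["production_rel_discrepancy"].dropna(), 0.0, atol=1e-9
        )
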