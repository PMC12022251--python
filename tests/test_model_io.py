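"""Data model, tabular schema I/O, boundaries and zonal extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from harvstat.errors import CRSMismatchError, InvariantError, SchemaError
from harvstat.io import (
    _finalize_units,
    equal_area_ha,
    read_boundaries,
    read_crop_table,
    write_boundaries,
    write_crop_table,
    zonal_cropland_area,
)
from harvstat.model import CANONICAL_COLUMNS, AdminUnit, CroplandRaster
from harvstat.synthetic import ScenarioConfig, make_crop_series


def _one_row(**overrides):
    row = {
        "fnid": "SY2000A201", "country": "Synthetica", "country_code": "SY",
        "admin_1": "Region 0", "admin_2": "District 0-1", "product": "maize",
        "season_name": "annual", "planting_year": 2005, "planting_month": 3,
        "harvest_year": 2005, "harvest_month": 11,
        "crop_production_system": "none", "qc_flag": 0,
        "area": 2.0, "production": 1.0, "yield": 0.5,
    }
    row.update(overrides)
    return pd.DataFrame([row], columns=CANONICAL_COLUMNS)


class TestCropTable:
    def test_single_valid_row_round_trip(self, tmp_path):
        df = _one_row()
        p = tmp_path / "t.csv"
        write_crop_table(df, p)
        back = read_crop_table(p, strict=True)
        assert len(back) == 1
        assert len(back.attrs["violations"]) == 0
        pd.testing.assert_frame_equal(df, back, check_dtype=False)

    def test_missing_column_is_schema_error_naming_it(self, tmp_path):
        df = _one_row().drop(columns=["qc_flag"])
        p = tmp_path / "t.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="qc_flag"):
            read_crop_table(p)

    def test_inconsistent_yield_rejected_in_strict_mode(self, tmp_path):
        # production/area = 0.5, reported yield 0.9
        df = _one_row(**{"yield": 0.9})
        p = tmp_path / "t.csv"
        df.to_csv(p, index=False)
        with pytest.raises(InvariantError, match="yield"):
            read_crop_table(p, strict=True)
        lenient = read_crop_table(p, strict=False)
        assert list(lenient.attrs["violations"]["problem"]) == [
            "yield inconsistent with production/area"
        ]

    def test_empty_collection_writes_header_only(self, tmp_path):
        p = tmp_path / "t.csv"
        write_crop_table(_one_row().iloc[0:0], p)
        assert p.read_text().strip() == ",".join(CANONICAL_COLUMNS)

    def test_missing_admin2_round_trips_as_empty_field(self, tmp_path):
        df = _one_row(admin_2=np.nan)
        p = tmp_path / "t.csv"
        write_crop_table(df, p)
        line = p.read_text().splitlines()[1]
        assert ",nan," not in line and ",NaN," not in line
        back = read_crop_table(p)
        assert back["admin_2"].isna().all()

    def test_missing_statistics_stay_missing_not_zero(self, tmp_path):
        df = _one_row(area=np.nan, production=np.nan, **{"yield": np.nan})
        p = tmp_path / "t.csv"
        write_crop_table(df, p)
        back = read_crop_table(p)
        assert back[["area", "production", "yield"]].isna().all().all()

    def test_non_numeric_statistic_reports_row_index(self, tmp_path):
        p = tmp_path / "t.csv"
        df = _one_row()
        df["production"] = "lots"
        df.to_csv(p, index=False)
        with pytest.raises(InvariantError, match="row 0"):
            read_crop_table(p, strict=True)

    def test_extra_columns_preserved_on_read_dropped_on_write(self, tmp_path):
        p = tmp_path / "t.csv"
        df = _one_row()
        df["source"] = "ministry"
        df.to_csv(p, index=False)
        back = read_crop_table(p)
        assert "source" in back.columns
        p2 = tmp_path / "t2.csv"
        write_crop_table(back, p2)
        assert "source" not in read_crop_table(p2).columns

    @given(seed=st.integers(0, 50))
    def test_round_trip_identity_on_generated_tables(self, tmp_path, seed):
        records, _ = make_crop_series(
            ScenarioConfig(seed=seed, n_admin1=1, n_admin2=2, n_years=6,
                           n_outliers=0, n_repeat_runs=0, reporting_prob=0.8)
        )
        p = tmp_path / f"rt{seed}.csv"
        write_crop_table(records, p)
        back = read_crop_table(p, strict=True)
        pd.testing.assert_frame_equal(
            records.reset_index(drop=True), back, check_dtype=False
        )


class TestBoundaries:
    def _units(self, n=4):
        return [
            AdminUnit(f"SY2000A2{i:02d}", "SY", 2, f"D{i}", box(i, 0, i + 1, 1), "2000")
            for i in range(n)
        ]

    @pytest.mark.parametrize("ext", ["geojson", "gpkg"])
    def test_round_trip(self, tmp_path, ext):
        units = self._units()
        p = tmp_path / f"b.{ext}"
        write_boundaries(units, p)
        back = read_boundaries(p)
        assert [u.fnid for u in back] == [u.fnid for u in units]
        for a, b in zip(units, back):
            assert a.geometry.equals(b.geometry)
            assert (a.level, a.name, a.vintage) == (b.level, b.name, b.vintage)

    def test_duplicate_fnid_rejected_naming_it(self, tmp_path):
        units = self._units(2)
        raw = [
            {"fnid": "DUP", "geometry": u.geometry, "level": 2} for u in units
        ]
        with pytest.raises(InvariantError, match="DUP"):
            _finalize_units(raw, None, "test")

    def test_bowtie_polygon_repaired_and_reported(self):
        bow = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        assert not bow.is_valid
        with pytest.warns(UserWarning, match="repaired"):
            units = _finalize_units(
                [{"fnid": "B1", "geometry": bow, "level": 2}], None, "test"
            )
        assert units[0].geometry.is_valid
        # zero-buffer resolves the self-intersection by winding, keeping the
        # consistently oriented lobe (one of the two 0.25 triangles)
        assert units[0].geometry.area == pytest.approx(0.25)

    def test_vintage_filter(self, tmp_path):
        units = self._units(2)
        units[1].vintage = "2010"
        p = tmp_path / "b.geojson"
        write_boundaries(units, p)
        assert [u.fnid for u in read_boundaries(p, vintage="2010")] == [units[1].fnid]

    def test_fixture_records_join_one_unit_per_vintage(self, plain_scenario):
        units = {u.fnid for u in plain_scenario.old_units}
        assert set(plain_scenario.records["fnid"]) <= units


class TestZonal:
    def _uniform(self):
        # 1 ha of cropland per 1-unit cell
        return CroplandRaster(np.ones((10, 10)), (0.0, 10.0, 1.0, 1.0))

    def test_polygon_covering_25_cells(self):
        assert zonal_cropland_area(self._uniform(), box(0, 5, 5, 10)) == pytest.approx(25.0)

    def test_half_covered_cells(self):
        # a strip covering the top half of ten cells
        assert zonal_cropland_area(self._uniform(), box(0, 9.5, 10, 10)) == pytest.approx(5.0)

    def test_off_raster_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="does not overlap"):
            assert zonal_cropland_area(self._uniform(), box(50, 50, 51, 51)) == 0.0

    def test_crs_mismatch_raises(self):
        r = CroplandRaster(np.ones((2, 2)), (0, 2, 1, 1), crs="EPSG:3857")
        with pytest.raises(CRSMismatchError):
            zonal_cropland_area(r, box(0, 0, 1, 1), geometry_crs="EPSG:4326")

    @given(
        cut=st.floats(0.5, 9.5),
        values_seed=st.integers(0, 20),
    )
    def test_additive_over_disjoint_partition(self, cut, values_seed):
        rng = np.random.default_rng(values_seed)
        raster = CroplandRaster(rng.uniform(0, 3, size=(10, 10)), (0.0, 10.0, 1.0, 1.0))
        left = box(0, 0, cut, 10)
        right = box(cut, 0, 10, 10)
        whole = box(0, 0, 10, 10)
        total = zonal_cropland_area(raster, whole)
        parts = zonal_cropland_area(raster, left) + zonal_cropland_area(raster, right)
        assert parts == pytest.approx(total, rel=1e-6)


class TestEqualArea:
    def test_planar_passthrough(self):
        assert equal_area_ha(box(0, 0, 2, 3), crs=None) == pytest.approx(6.0)

    def test_geographic_square_matches_spherical_patch(self):
        # 1°x1° at the equator ~ (111.195 km)^2; sinusoidal is equal-area
        g = box(0, -0.5, 1, 0.5)
        expected_m2 = (np.pi / 180 * 6_371_007.181) ** 2  # cos(lat)≈1 integral
        assert equal_area_ha(g, crs="EPSG:4326") == pytest.approx(
            expected_m2 / 1e4, rel=1e-3
        )
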