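"""Readers and writers for the standard file formats.

Tabular crop statistics travel as UTF-8 comma-separated files in the fixed
16-column schema (``model.CANONICAL_COLUMNS``); empty fields are missing
values.  Administrative boundaries are read from GeoPackage or GeoJSON;
the cropland surface from GeoTIFF (ModelPixelScale / ModelTiepoint
georeferencing) via tifffile.

The GeoPackage support here is deliberately minimal: a GeoPackage is an
SQLite database with a documented geometry-blob encoding (a short "GP"
header followed by ISO WKB), which the standard-library ``sqlite3`` module
plus shapely's WKB codec handle directly.  Only simple feature tables with
2-D (multi)polygons are supported, which is all a boundary vintage needs.
"""

from __future__ import annotations

import datetime
import json
import math
import sqlite3
import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.wkb
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import CRSMismatchError, InvariantError, SchemaError
from .model import (
    CANONICAL_COLUMNS,
    AdminUnit,
    CroplandRaster,
    check_record_invariants,
)

_STRING_COLUMNS = [
    "fnid",
    "country",
    "country_code",
    "admin_1",
    "admin_2",
    "product",
    "season_name",
    "crop_production_system",
]
_INT_COLUMNS = ["planting_year", "planting_month", "harvest_year", "harvest_month", "qc_flag"]
_FLOAT_COLUMNS = ["area", "production", "yield"]

#: Mean ("authalic") Earth radius in metres, used by the built-in
#: sinusoidal equal-area projection for geographic coordinates.
EARTH_RADIUS_M = 6_371_007.181

#: Default equal-area convention for geographic inputs.
DEFAULT_EQUAL_AREA = "sinusoidal"

_GEOGRAPHIC_CRS = {"epsg:4326", "wgs84", "crs84", "ogc:crs84", "wgs 84"}


# ---------------------------------------------------------------------------
# Tabular crop statistics (Table-2 style CSV)
# ---------------------------------------------------------------------------

def read_crop_table(path, strict: bool = True) -> pd.DataFrame:
    """Read a crop-statistics CSV into the canonical DataFrame.

    Parameters
    ----------
    path
        CSV with a header containing all 16 canonical column names.  Extra
        columns are preserved (after the canonical ones).
    strict
        If True, any invariant violation raises :class:`InvariantError`.
        If False, violations are collected into ``df.attrs["violations"]``
        (a DataFrame with columns ``row`` and ``problem``) and the rows kept.

    Missing values (empty fields) are preserved as NaN, never coerced to 0.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in raw.columns if c not in CANONICAL_COLUMNS]
    df = raw[CANONICAL_COLUMNS + extra].copy()

    problems: list[dict] = []
    for col in _STRING_COLUMNS:
        df[col] = df[col].where(df[col] != "", np.nan)
    for col in _INT_COLUMNS + _FLOAT_COLUMNS:
        blank = df[col].str.strip() == ""
        num = pd.to_numeric(df[col].where(~blank, np.nan), errors="coerce")
        bad = num.isna() & ~blank
        for idx in df.index[bad]:
            problems.append({"row": idx, "problem": f"non-numeric value in '{col}'"})
        df[col] = num
    # A blank qc_flag means "not yet checked"; carry it as 0 (no flag).
    df["qc_flag"] = df["qc_flag"].fillna(0)
    for col in _INT_COLUMNS:
        if df[col].isna().any():
            for idx in df.index[df[col].isna()]:
                problems.append({"row": idx, "problem": f"missing value in '{col}'"})
            df[col] = df[col].astype("Int64")
        else:
            df[col] = df[col].astype(np.int64)

    report = pd.concat(
        [pd.DataFrame(problems, columns=["row", "problem"]), check_record_invariants(df)],
        ignore_index=True,
    )
    if strict and len(report):
        lines = "; ".join(f"row {r.row}: {r.problem}" for r in report.itertuples())
        raise InvariantError(f"{len(report)} invalid row(s): {lines}")
    df.attrs["violations"] = report
    return df


def write_crop_table(records: pd.DataFrame, path) -> None:
    """Write records to CSV in canonical column order.

    Missing cells become empty fields (not the string "NaN"); extra columns
    are dropped.  ``read_crop_table(write_crop_table(x))`` round-trips.
    """
    out = records[CANONICAL_COLUMNS].copy()
    for col in _INT_COLUMNS:
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, na_rep="")


def dataset_census(records: pd.DataFrame) -> dict:
    """Summary counts of a harmonized table: records, per-statistic counts,
    countries, and crop types."""
    return {
        "n_records": int(len(records)),
        "n_production": int(records["production"].notna().sum()),
        "n_area": int(records["area"].notna().sum()),
        "n_yield": int(records["yield"].notna().sum()),
        "n_countries": int(records["country_code"].nunique()),
        "n_products": int(records["product"].nunique()),
    }


# ---------------------------------------------------------------------------
# Equal-area handling
# ---------------------------------------------------------------------------

def is_geographic(crs: str | None) -> bool:
    return crs is not None and crs.strip().lower() in _GEOGRAPHIC_CRS


def to_equal_area(geometry: BaseGeometry, crs: str | None) -> BaseGeometry:
    """Project a geometry to an equal-area plane before area computation.

    Planar inputs (``crs`` None or non-geographic) are returned unchanged
    and assumed already equal-area.  Geographic (lon/lat degree) inputs are
    projected with the world sinusoidal projection, which is equal-area by
    construction: x = R·λ·cos(φ), y = R·φ.
    """
    if not is_geographic(crs):
        return geometry

    def _project(coords: np.ndarray) -> np.ndarray:
        lon = np.radians(coords[:, 0])
        lat = np.radians(coords[:, 1])
        return np.column_stack(
            [EARTH_RADIUS_M * lon * np.cos(lat), EARTH_RADIUS_M * lat]
        )

    return shapely.transform(geometry, _project)


def equal_area_ha(geometry: BaseGeometry, crs: str | None = None) -> float:
    """Polygon area in hectares, via :func:`to_equal_area` when geographic.

    Planar coordinates are interpreted as metres unless already hectares;
    callers working on synthetic integer grids usually treat planar area as
    being in the grid's own units and should use ``geometry.area`` directly.
    """
    g = to_equal_area(geometry, crs)
    return g.area / 1e4 if is_geographic(crs) else g.area


# ---------------------------------------------------------------------------
# Boundary vintages: GeoJSON and minimal GeoPackage
# ---------------------------------------------------------------------------

_UNIT_FIELDS = ["fnid", "country_code", "level", "name", "vintage"]


def _finalize_units(raw: list[dict], crs: str | None, where: str) -> list[AdminUnit]:
    """Repair trivially invalid geometries (zero-buffer convention), reject
    the irreparable, and enforce fnid uniqueness within the collection."""
    units: list[AdminUnit] = []
    seen: set[str] = set()
    rejected: list[str] = []
    for rec in raw:
        geom = rec["geometry"]
        if geom is None or geom.is_empty:
            rejected.append(str(rec.get("fnid")))
            continue
        if not geom.is_valid:
            repaired = geom.buffer(0)
            if repaired.is_valid and not repaired.is_empty and not math.isclose(
                repaired.area, 0.0
            ):
                warnings.warn(
                    f"{where}: geometry of {rec['fnid']} repaired with zero-buffer",
                    stacklevel=3,
                )
                geom = repaired
            else:
                rejected.append(str(rec["fnid"]))
                continue
        fnid = rec["fnid"]
        if fnid in seen:
            raise InvariantError(f"{where}: duplicate fnid '{fnid}' within vintage")
        seen.add(fnid)
        units.append(
            AdminUnit(
                fnid=fnid,
                country_code=rec.get("country_code", ""),
                level=int(rec.get("level", 1)),
                name=rec.get("name", fnid),
                geometry=geom,
                vintage=str(rec.get("vintage", "")),
                crs=crs,
            )
        )
    if rejected:
        raise InvariantError(
            f"{where}: irreparable geometry for fnid(s): {', '.join(rejected)}"
        )
    if not units:
        raise InvariantError(f"{where}: no usable features")
    return units


def read_boundaries(path, vintage: str | None = None, layer: str | None = None) -> list[AdminUnit]:
    """Read administrative units from a GeoPackage (.gpkg) or GeoJSON file.

    ``vintage`` filters on the feature-level ``vintage`` attribute when
    given.  Every feature must carry an ``fnid`` attribute; fnids must be
    unique within the selected vintage.
    """
    path = Path(path)
    if path.suffix.lower() == ".gpkg":
        raw, crs = _read_gpkg(path, layer)
    else:
        raw, crs = _read_geojson(path)
    if vintage is not None:
        raw = [r for r in raw if str(r.get("vintage", "")) == str(vintage)]
    return _finalize_units(raw, crs, where=path.name)


def write_boundaries(units: list[AdminUnit], path, layer: str = "admin_units") -> None:
    """Write units to GeoPackage or GeoJSON, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".gpkg":
        _write_gpkg(units, path, layer)
    else:
        _write_geojson(units, path)


def _read_geojson(path: Path) -> tuple[list[dict], str | None]:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    if not feats:
        raise InvariantError(f"{path.name}: empty feature collection")
    crs = None
    if isinstance(gj.get("crs"), dict):
        crs = gj["crs"].get("properties", {}).get("name")
    raw = []
    for feat in feats:
        props = dict(feat.get("properties") or {})
        if "fnid" not in props:
            raise InvariantError(f"{path.name}: feature without 'fnid' attribute")
        props["geometry"] = shape(feat["geometry"]) if feat.get("geometry") else None
        raw.append(props)
    return raw, crs


def _write_geojson(units: list[AdminUnit], path: Path) -> None:
    gj: dict = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {
                    "fnid": u.fnid,
                    "country_code": u.country_code,
                    "level": u.level,
                    "name": u.name,
                    "vintage": u.vintage,
                },
                "geometry": mapping(u.geometry),
            }
            for u in units
        ],
    }
    crs = units[0].crs if units else None
    if crs:
        gj["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(gj, fh)


# --- GeoPackage geometry blob codec ---------------------------------------

_GPKG_ENVELOPE_BYTES = {0: 0, 1: 32, 2: 48, 3: 48, 4: 64}


def _gpkg_blob_to_geometry(blob: bytes) -> BaseGeometry:
    if blob[:2] != b"GP":
        raise SchemaError("not a GeoPackage geometry blob")
    flags = blob[3]
    envelope_code = (flags >> 1) & 0x07
    header_len = 8 + _GPKG_ENVELOPE_BYTES[envelope_code]
    return shapely.wkb.loads(blob[header_len:])


def _geometry_to_gpkg_blob(geometry: BaseGeometry, srs_id: int = 0) -> bytes:
    header = b"GP" + bytes([0, 0b00000001]) + struct.pack("<i", srs_id)
    return header + shapely.wkb.dumps(geometry, byte_order=1)


def _read_gpkg(path: Path, layer: str | None) -> tuple[list[dict], str | None]:
    con = sqlite3.connect(path)
    try:
        layers = dict(
            con.execute(
                "SELECT table_name, srs_id FROM gpkg_geometry_columns"
            ).fetchall()
        )
        if not layers:
            raise SchemaError(f"{path.name}: no feature layers")
        if layer is None:
            if len(layers) > 1:
                raise SchemaError(
                    f"{path.name}: multiple layers {sorted(layers)}; pass layer="
                )
            layer = next(iter(layers))
        elif layer not in layers:
            raise SchemaError(f"{path.name}: no such layer '{layer}'")
        geom_col = con.execute(
            "SELECT column_name FROM gpkg_geometry_columns WHERE table_name = ?",
            (layer,),
        ).fetchone()[0]
        crs_row = con.execute(
            "SELECT organization, organization_coordsys_id FROM gpkg_spatial_ref_sys "
            "WHERE srs_id = ?",
            (layers[layer],),
        ).fetchone()
        crs = f"{crs_row[0]}:{crs_row[1]}" if crs_row and crs_row[0] else None
        cols = [r[1] for r in con.execute(f'PRAGMA table_info("{layer}")')]
        if "fnid" not in cols:
            raise InvariantError(f"{path.name}: layer '{layer}' has no 'fnid' attribute")
        attr_cols = [c for c in cols if c not in (geom_col, "fid")]
        rows = con.execute(
            f'SELECT {", ".join(chr(34) + c + chr(34) for c in attr_cols)}, '
            f'"{geom_col}" FROM "{layer}"'
        ).fetchall()
        if not rows:
            raise InvariantError(f"{path.name}: layer '{layer}' is empty")
        raw = []
        for row in rows:
            rec = dict(zip(attr_cols, row[:-1]))
            rec["geometry"] = _gpkg_blob_to_geometry(row[-1]) if row[-1] else None
            raw.append(rec)
        return raw, crs
    finally:
        con.close()


def _write_gpkg(units: list[AdminUnit], path: Path, layer: str) -> None:
    if path.exists():
        path.unlink()
    crs = units[0].crs if units else None
    if is_geographic(crs):
        srs_id, org, org_id, definition = 4326, "EPSG", 4326, "GEOGCS[\"WGS 84\"]"
    else:
        srs_id, org, org_id = 0, "NONE", 0
        definition = "undefined cartesian (assumed equal-area planar)"
    con = sqlite3.connect(path)
    try:
        con.executescript(
            """
            PRAGMA application_id = 0x47504B47;
            PRAGMA user_version = 10300;
            CREATE TABLE gpkg_spatial_ref_sys (
              srs_name TEXT NOT NULL, srs_id INTEGER PRIMARY KEY,
              organization TEXT NOT NULL, organization_coordsys_id INTEGER NOT NULL,
              definition TEXT NOT NULL, description TEXT);
            CREATE TABLE gpkg_contents (
              table_name TEXT PRIMARY KEY, data_type TEXT NOT NULL,
              identifier TEXT UNIQUE, description TEXT DEFAULT '',
              last_change DATETIME, min_x DOUBLE, min_y DOUBLE,
              max_x DOUBLE, max_y DOUBLE, srs_id INTEGER);
            CREATE TABLE gpkg_geometry_columns (
              table_name TEXT NOT NULL, column_name TEXT NOT NULL,
              geometry_type_name TEXT NOT NULL, srs_id INTEGER NOT NULL,
              z TINYINT NOT NULL, m TINYINT NOT NULL,
              CONSTRAINT pk_geom_cols PRIMARY KEY (table_name, column_name));
            """
        )
        con.execute(
            "INSERT INTO gpkg_spatial_ref_sys VALUES (?, ?, ?, ?, ?, NULL)",
            (str(crs or "undefined"), srs_id, org, org_id, definition),
        )
        bounds = shapely.unary_union([u.geometry for u in units]).bounds
        con.execute(
            "INSERT INTO gpkg_contents VALUES (?, 'features', ?, '', ?, ?, ?, ?, ?, ?)",
            (layer, layer, datetime.datetime.now(datetime.timezone.utc).isoformat(),
             *bounds, srs_id),
        )
        con.execute(
            "INSERT INTO gpkg_geometry_columns VALUES (?, 'geom', 'MULTIPOLYGON', ?, 0, 0)",
            (layer, srs_id),
        )
        con.execute(
            f'CREATE TABLE "{layer}" (fid INTEGER PRIMARY KEY AUTOINCREMENT, '
            "geom BLOB, fnid TEXT, country_code TEXT, level INTEGER, "
            "name TEXT, vintage TEXT)"
        )
        con.executemany(
            f'INSERT INTO "{layer}" (geom, fnid, country_code, level, name, vintage) '
            "VALUES (?, ?, ?, ?, ?, ?)",
            [
                (
                    _geometry_to_gpkg_blob(u.geometry, srs_id),
                    u.fnid, u.country_code, u.level, u.name, u.vintage,
                )
                for u in units
            ],
        )
        con.commit()
    finally:
        con.close()


# ---------------------------------------------------------------------------
# Cropland raster: GeoTIFF via tifffile, zonal extraction via shapely
# ---------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


def write_cropland_raster(raster: CroplandRaster, path) -> None:
    """Write a CroplandRaster as a single-band GeoTIFF (north-up grid)."""
    import tifffile

    x0, y0, dx, dy = raster.transform
    description = json.dumps({"crs": raster.crs, "units": "ha per cell"})
    tifffile.imwrite(
        path,
        raster.values.astype(np.float64),
        photometric="minisblack",
        description=description,
        extratags=[
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (dx, dy, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        ],
    )


def read_cropland_raster(path) -> CroplandRaster:
    """Read a single-band GeoTIFF written with pixel-scale/tiepoint tags."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise SchemaError(f"{path}: GeoTIFF lacks georeferencing tags")
        dx, dy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
        i, j, _, x, y, _ = tags[_TAG_MODEL_TIEPOINT].value[:6]
        x0, y0 = x - i * dx, y + j * dy
        crs = None
        desc = tags.get(270)
        if desc is not None:
            try:
                crs = json.loads(desc.value).get("crs")
            except (ValueError, AttributeError):
                crs = None
    return CroplandRaster(values=values, transform=(x0, y0, dx, dy), crs=crs)


def zonal_cropland_area(
    raster: CroplandRaster,
    geometry: BaseGeometry,
    geometry_crs: str | None = None,
) -> float:
    """Cropland area (ha) of a polygon: Σ cell value × covered cell fraction.

    Partial cells contribute by exact polygon–cell intersection area, not by
    cell-centre sampling, so small units are weighted accurately.  A
    geometry disjoint from the raster returns 0 with a warning.
    """
    if (
        geometry_crs is not None
        and raster.crs is not None
        and geometry_crs.strip().lower() != raster.crs.strip().lower()
    ):
        raise CRSMismatchError(
            f"geometry CRS '{geometry_crs}' != raster CRS '{raster.crs}'"
        )
    x0, y0, dx, dy = raster.transform
    nrow, ncol = raster.shape
    gxmin, gymin, gxmax, gymax = geometry.bounds
    rxmin, rymin, rxmax, rymax = raster.bounds
    if gxmax <= rxmin or gxmin >= rxmax or gymax <= rymin or gymin >= rymax:
        warnings.warn("geometry does not overlap raster extent; zonal area is 0")
        return 0.0

    c0 = max(0, int(math.floor((gxmin - x0) / dx)))
    c1 = min(ncol, int(math.ceil((gxmax - x0) / dx)))
    r0 = max(0, int(math.floor((y0 - gymax) / dy)))
    r1 = min(nrow, int(math.ceil((y0 - gymin) / dy)))
    if c1 <= c0 or r1 <= r0:
        warnings.warn("geometry does not overlap raster extent; zonal area is 0")
        return 0.0

    rows, cols = np.mgrid[r0:r1, c0:c1]
    rows, cols = rows.ravel(), cols.ravel()
    xmins = x0 + cols * dx
    ymaxs = y0 - rows * dy
    cells = shapely.box(xmins, ymaxs - dy, xmins + dx, ymaxs)
    fractions = shapely.area(shapely.intersection(cells, geometry)) / (dx * dy)
    return float(np.sum(fractions * raster.values[rows, cols]))
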