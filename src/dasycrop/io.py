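"""Readers and writers for the pipeline's file formats.

Rasters are single-band float32 GeoTIFFs in geographic coordinates
(WGS84), georeferenced with the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory) and a GDAL-style nodata tag.  Admin
units are GeoJSON FeatureCollections with ``unit_id``, ``country`` and
``level`` properties.  Tables are comma-separated UTF-8 CSV with "."
decimals and empty fields for missing values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .allocate import AllocationConfig, AllocationGrid, DisaggregationResult
from .errors import ParameterError, SchemaError
from .grid import AdminLayer, AdminUnit, GridSpec, PopulationGrid
from .impute import BBoxFill
from .standardize import QUANTITY_KINDS, CensusRecord, NationalTotal

# GeoTIFF / GDAL tag codes
_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_NODATA = 42113

# GeoKeyDirectory: geographic model, pixel-is-area, EPSG:4326
_GEOKEYS = (1, 1, 0, 3,
            1024, 0, 1, 2,
            1025, 0, 1, 1,
            2048, 0, 1, 4326)

PathLike = Union[str, Path]


def write_raster(path: PathLike, spec: GridSpec, values: np.ndarray) -> None:
    """Write a float32 GeoTIFF; NaN becomes the spec's nodata sentinel."""
    data = np.asarray(values, dtype=np.float32).copy()
    data[~np.isfinite(data)] = np.float32(spec.nodata)
    d = spec.cell_deg
    extratags = [
        (_TAG_PIXELSCALE, "d", 3, (d, d, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0,
                                 spec.origin_lon, spec.origin_lat, 0.0)),
        (_TAG_GEOKEYS, "H", len(_GEOKEYS), _GEOKEYS),
        (_TAG_NODATA, "s", 0, str(spec.nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_raster(path: PathLike) -> Tuple[GridSpec, np.ndarray]:
    """Read a GeoTIFF written by :func:`write_raster` (or GDAL-compatible).

    Returns the grid spec and a float64 array with nodata as NaN.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(np.float64)
        tags = page.tags
        if _TAG_PIXELSCALE not in tags or _TAG_TIEPOINT not in tags:
            raise SchemaError(f"{path}: missing GeoTIFF georeferencing tags")
        scale = tags[_TAG_PIXELSCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata = float(tags[_TAG_NODATA].value) if _TAG_NODATA in tags else -9999.0
    if data.ndim != 2:
        raise SchemaError(f"{path}: expected a single-band raster")
    # kill float32/tag round-trip noise at the sub-micro-arcsecond level
    cell = round(scale[0] * 3600.0, 9)
    spec = GridSpec(origin_lon=round(tie[3], 12), origin_lat=round(tie[4], 12),
                    n_rows=data.shape[0], n_cols=data.shape[1],
                    cell_size=cell, nodata=nodata)
    data[data == nodata] = np.nan
    return spec, data


def read_population(path: PathLike) -> PopulationGrid:
    spec, data = read_raster(path)
    return PopulationGrid(spec, data)


def write_admin_geojson(layer: AdminLayer, path: PathLike) -> None:
    features = [
        {"type": "Feature",
         "properties": {"unit_id": u.unit_id, "country": u.country,
                        "level": u.level},
         "geometry": mapping(u.geometry)}
        for u in layer
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}))


def read_admin_geojson(path: PathLike) -> AdminLayer:
    """Read admin polygons; requires unit_id, country and level properties."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    feats = doc.get("features")
    if feats is None:
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    units = []
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        for col in ("unit_id", "country", "level"):
            if col not in props:
                raise SchemaError(
                    f"{path}: feature {i} lacks required property {col!r}")
        units.append(AdminUnit(unit_id=str(props["unit_id"]),
                               country=str(props["country"]),
                               level=int(props["level"]),
                               geometry=shape(f["geometry"])))
    return AdminLayer(units)


def _parse_float(value, path: PathLike, column: str, row: int,
                 allow_missing: bool = False) -> Optional[float]:
    if value is None or (isinstance(value, str) and value.strip() == "") \
            or (isinstance(value, float) and math.isnan(value)):
        if allow_missing:
            return None
        raise SchemaError(f"{path}: column {column!r}, row {row}: value required")
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{path}: column {column!r}, row {row}: non-numeric value {value!r}")
    if out < 0:
        raise SchemaError(
            f"{path}: column {column!r}, row {row}: negative value {out}")
    return out


def _require_columns(df: pd.DataFrame, cols: List[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_census_csv(path: PathLike) -> List[CensusRecord]:
    """Columns: unit_id, country, quantity_kind, value, [year], [source]."""
    df = pd.read_csv(path, dtype={"unit_id": str, "country": str})
    _require_columns(df, ["unit_id", "country", "quantity_kind", "value"], path)
    records = []
    for i, row in df.iterrows():
        kind = str(row["quantity_kind"])
        if kind not in QUANTITY_KINDS:
            raise SchemaError(
                f"{path}: column 'quantity_kind', row {i}: unknown kind {kind!r}")
        value = _parse_float(row["value"], path, "value", i, allow_missing=True)
        year = int(row["year"]) if "year" in df.columns and pd.notna(row.get("year")) else 0
        source = str(row["source"]) if "source" in df.columns and pd.notna(row.get("source")) else ""
        records.append(CensusRecord(str(row["unit_id"]), str(row["country"]),
                                    kind, value, census_year=year, source=source))
    return records


def read_totals_csv(path: PathLike) -> List[NationalTotal]:
    """Columns: country, quantity_kind, reference_value, [reference_year]."""
    df = pd.read_csv(path, dtype={"country": str})
    _require_columns(df, ["country", "quantity_kind", "reference_value"], path)
    totals = []
    for i, row in df.iterrows():
        kind = str(row["quantity_kind"])
        if kind not in QUANTITY_KINDS:
            raise SchemaError(
                f"{path}: column 'quantity_kind', row {i}: unknown kind {kind!r}")
        value = _parse_float(row["reference_value"], path, "reference_value", i)
        year = int(row["reference_year"]) if "reference_year" in df.columns else 2014
        totals.append(NationalTotal(str(row["country"]), kind, value, year))
    return totals


def read_groups_csv(path: PathLike) -> Dict[str, str]:
    """Columns: unit_id, group.  Each unit_id may appear at most once."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["unit_id", "group"], path)
    if df["unit_id"].duplicated().any():
        dup = df.loc[df["unit_id"].duplicated(), "unit_id"].iloc[0]
        raise SchemaError(f"{path}: unit_id {dup!r} listed more than once")
    return dict(zip(df["unit_id"], df["group"]))


def read_bbox_fills_csv(path: PathLike) -> List[BBoxFill]:
    """Columns: min_lon, min_lat, max_lon, max_lat, constant_rate."""
    df = pd.read_csv(path)
    _require_columns(df, ["min_lon", "min_lat", "max_lon", "max_lat",
                          "constant_rate"], path)
    return [BBoxFill(float(r.min_lon), float(r.min_lat), float(r.max_lon),
                     float(r.max_lat), float(r.constant_rate))
            for r in df.itertuples()]


#: Report column -> human-readable meaning, written as the legend file.
LEGEND: Dict[str, str] = {
    "unit_id": "Administrative unit identifier",
    "country": "Country code of the unit",
    "quantity_kind": "production (tonnes) or harvested_area (hectares)",
    "source": "Census data source tag",
    "admin_level": "Administrative level of the unit (0 = national)",
    "census_year": "Year of the raw census record (0 = unknown)",
    "zonal_pop": "Rural population sum over the unit's pixels (people)",
    "raw_value": "Raw census value; empty when missing",
    "country_raw_sum": "Sum of non-missing raw values in the unit's country",
    "national_reference": "National reference-year total used for scaling",
    "adjusted_value": "Unit value rescaled to the national reference total",
    "rate": "Per-capita rate used for allocation (quantity per person)",
    "imputed": "True if the rate came from neighbour/group imputation",
    "n_pixels": "Number of grid pixels assigned to the unit",
    "n_capped": "Pixels held at the per-pixel cap after redistribution",
    "iterations": "Water-filling iterations run for the unit",
    "residual": "Mass that could not be placed (infeasible units only)",
    "status": "ok | infeasible | zero-population | no-pixels",
}

REPORT_COLUMNS = list(LEGEND)


@dataclass
class RunConfig:
    """Paths and options for one CLI disaggregation run."""

    population_path: Path
    admin_path: Path
    census_path: Path
    totals_path: Path
    out_dir: Path
    quantity_kind: str = "production"
    groups_path: Optional[Path] = None
    bbox_fills_path: Optional[Path] = None
    allocation: AllocationConfig = field(default_factory=AllocationConfig)


def read_inputs(cfg: RunConfig):
    """Load and validate the full input bundle for a run."""
    pop = read_population(cfg.population_path)
    layer = read_admin_geojson(cfg.admin_path)
    census = read_census_csv(cfg.census_path)
    totals = read_totals_csv(cfg.totals_path)
    groups = read_groups_csv(cfg.groups_path) if cfg.groups_path else None
    fills = read_bbox_fills_csv(cfg.bbox_fills_path) if cfg.bbox_fills_path else None
    return pop, layer, census, totals, groups, fills


def write_outputs(result: DisaggregationResult, out_dir: PathLike) -> Dict[str, Path]:
    """Write the grid, report, imputation log and legend for one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kind = result.grid.quantity_kind
    paths = {
        "grid": out / f"{kind}_grid.tif",
        "report": out / f"{kind}_report.csv",
        "imputation_log": out / "imputation_log.csv",
        "legend": out / "legend.csv",
    }
    write_raster(paths["grid"], result.grid.spec, result.grid.values)
    report = result.report.reindex(columns=REPORT_COLUMNS)
    report.to_csv(paths["report"], index=False)
    result.imputation_log.to_csv(paths["imputation_log"], index=False)
    legend = pd.DataFrame(
        {"column": list(LEGEND), "description": list(LEGEND.values())})
    legend.to_csv(paths["legend"], index=False)
    return paths
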