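"""File I/O for the pipeline's plain-text artifact formats.

Every writer has a reader and all roundtrips are lossless at the
documented precision: district/station/score tables as CSV, rasters as
ESRI ASCII grids (8 significant digits), polygons and vulnerability maps
as GeoJSON FeatureCollections (WGS84 lon/lat), run configuration as TOML.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .errors import FormatError, SchemaError, TableParseError
from .interpolation import GridSpec, RasterGrid

__all__ = [
    "read_district_csv",
    "write_district_csv",
    "read_stations_csv",
    "write_stations_csv",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_geojson",
    "read_geojson",
    "load_toml_config",
]


# ---------------------------------------------------------------------------
# district table
# ---------------------------------------------------------------------------

def read_district_csv(path, covariates=None) -> pd.DataFrame:
    """Read and validate a district table (district_id, covariates, case_count).

    Row order is preserved. Counts must be non-negative integers; parse
    errors cite the 1-based data row.
    """
    df = pd.read_csv(path)
    if "district_id" not in df.columns:
        raise SchemaError("missing column 'district_id'")
    if "case_count" not in df.columns:
        raise SchemaError("missing column 'case_count'")
    if covariates is not None:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise SchemaError(f"missing covariate column(s): {missing}")
    for i, raw in enumerate(df["case_count"], start=1):
        try:
            v = float(raw)
        except (TypeError, ValueError):
            raise TableParseError(f"row {i}: case_count {raw!r} is not a number", row=i)
        if not np.isfinite(v) or v != int(v) or v < 0:
            raise TableParseError(
                f"row {i}: case_count {raw!r} is not a non-negative integer", row=i
            )
    df["case_count"] = df["case_count"].astype(int)
    other = [c for c in df.columns if c not in ("district_id", "case_count")]
    for c in other:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df[c].apply(lambda x: not isinstance(x, (int, float))).idxmax()
            raise TableParseError(
                f"row {bad + 1}: covariate {c!r} is not numeric", row=int(bad) + 1
            )
    return df


def write_district_csv(df: pd.DataFrame, path) -> None:
    cols = ["district_id"] + [
        c for c in df.columns if c not in ("district_id", "case_count")
    ]
    if "case_count" in df.columns:
        cols.append("case_count")
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stations
# ---------------------------------------------------------------------------

def read_stations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"station_id", "lon", "lat", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"stations file missing column(s): {sorted(missing)}")
    return df


def write_stations_csv(df: pd.DataFrame, path) -> None:
    df[["station_id", "lon", "lat", "value"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: RasterGrid, path) -> None:
    """ESRI ASCII grid: 6-line header then rows from the top (north) down.

    Values are written with 8 significant digits, so roundtrips are exact
    to well under one part in 10^6.
    """
    spec = raster.spec
    lines = [
        f"ncols {spec.n_cols}",
        f"nrows {spec.n_rows}",
        f"xllcorner {spec.origin_lon:.10g}",
        f"yllcorner {spec.origin_lat:.10g}",
        f"cellsize {spec.cell_size:.10g}",
        f"NODATA_value {raster.nodata:.10g}",
    ]
    for r in range(spec.n_rows - 1, -1, -1):  # internal row 0 = south
        lines.append(" ".join(f"{v:.8g}" for v in raster.values[r]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path) -> RasterGrid:
    text = Path(path).read_text().strip().splitlines()
    if len(text) < 7:
        raise FormatError("ASCII grid too short for header + data")
    header = {}
    for line in text[:6]:
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"bad header line: {line!r}")
        header[parts[0].lower()] = parts[1]
    required = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"]
    missing = [k for k in required if k not in header]
    if missing:
        raise FormatError(f"ASCII grid header missing: {missing}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    rows = [np.array(line.split(), dtype=float) for line in text[6:]]
    data = np.vstack(rows)
    if data.shape != (n_rows, n_cols):
        raise FormatError(
            f"data shape {data.shape} does not match header ({n_rows}, {n_cols})"
        )
    spec = GridSpec(
        origin_lon=float(header["xllcorner"]),
        origin_lat=float(header["yllcorner"]),
        cell_size=float(header["cellsize"]),
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return RasterGrid(spec, data[::-1], nodata=float(header["nodata_value"]))


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def write_geojson(
    polygons: Mapping[str, Polygon] | dict,
    path,
    properties: Mapping[str, Mapping] | None = None,
) -> None:
    """Write polygons (or a ready-made FeatureCollection dict) as GeoJSON."""
    if isinstance(polygons, dict) and polygons.get("type") == "FeatureCollection":
        collection = polygons
    else:
        features = []
        for district_id, poly in polygons.items():
            props = {"district_id": district_id}
            if properties and district_id in properties:
                props.update(properties[district_id])
            features.append(
                {"type": "Feature", "properties": props, "geometry": mapping(poly)}
            )
        collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, separators=(",", ":")) + "\n")


def read_geojson(path) -> tuple[dict[str, Polygon], dict[str, dict]]:
    """Read a FeatureCollection back into (polygons, per-district properties)."""
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise FormatError("not a GeoJSON FeatureCollection")
    polygons: dict[str, Polygon] = {}
    props: dict[str, dict] = {}
    for feat in data.get("features", []):
        p = feat.get("properties", {})
        did = p.get("district_id")
        if did is None:
            raise FormatError("feature without district_id property")
        polygons[did] = shape(feat["geometry"])
        props[did] = p
    return polygons, props


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_toml_config(path) -> dict:
    """Plain key-value TOML file mirroring PipelineConfig sections."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
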