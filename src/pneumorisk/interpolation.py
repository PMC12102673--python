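"""Inverse-distance-weighted interpolation and zonal aggregation.

Station point measurements are interpolated onto a regular lon/lat raster
with IDW weights w_i = d_i^(-p) (an exact interpolator: a cell center
coinciding with a station recovers the station value), then averaged per
district polygon by a cell-center-in-polygon rule.

Distances are planar degrees: at the study's ~1.5 degree extent on the
equator the geodesic distortion is negligible, and the raster header
documents the convention. Grid convention: lower-left origin, row 0 is the
southernmost row, cell centers at origin + (index + 0.5) * cell_size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .errors import EmptyZoneError, InvalidArgumentError

__all__ = ["RasterGrid", "GridSpec", "IdwConfig", "idw_interpolate", "zonal_mean",
           "grid_for_bbox"]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster: lower-left corner, cell size, shape."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise InvalidArgumentError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidArgumentError("grid must have at least one row and column")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) meshgrids of cell centers, shape (n_rows, n_cols)."""
        lons = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lats = self.origin_lat + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lons, lats)


def grid_for_bbox(bbox, cell_size: float = 0.01) -> GridSpec:
    """Smallest grid of ``cell_size`` cells anchored at the bbox lower-left
    corner that covers the bbox."""
    lon0, lat0, lon1, lat1 = bbox
    if not (lon1 > lon0 and lat1 > lat0):
        raise InvalidArgumentError(f"degenerate bbox {bbox}")
    n_cols = int(np.ceil((lon1 - lon0) / cell_size - 1e-12))
    n_rows = int(np.ceil((lat1 - lat0) / cell_size - 1e-12))
    return GridSpec(lon0, lat0, cell_size, n_rows, n_cols)


@dataclass(frozen=True)
class IdwConfig:
    """IDW parameters: weight exponent, optional k-nearest cut, snap radius."""

    power: float = 2.0
    max_stations: int | None = None
    snap_tolerance: float = 1e-9

    def __post_init__(self):
        if self.power <= 0:
            raise InvalidArgumentError("power must be > 0")
        if self.max_stations is not None and self.max_stations < 1:
            raise InvalidArgumentError("max_stations must be >= 1")


@dataclass
class RasterGrid:
    """Regular lon/lat raster. ``values`` is (n_rows, n_cols), row 0 = south."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise InvalidArgumentError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def n_rows(self) -> int:
        return self.spec.n_rows

    @property
    def n_cols(self) -> int:
        return self.spec.n_cols


def _station_arrays(stations) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(stations, pd.DataFrame):
        missing = {"lon", "lat", "value"} - set(stations.columns)
        if missing:
            raise InvalidArgumentError(f"stations missing columns: {sorted(missing)}")
        lon = stations["lon"].to_numpy(dtype=float)
        lat = stations["lat"].to_numpy(dtype=float)
        val = stations["value"].to_numpy(dtype=float)
    else:
        arr = np.asarray(stations, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise InvalidArgumentError("stations must be a (lon, lat, value) table")
        lon, lat, val = arr[:, 0], arr[:, 1], arr[:, 2]
    if lon.size == 0:
        raise InvalidArgumentError("station list is empty")
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat)) and np.all(np.isfinite(val))):
        raise InvalidArgumentError("stations contain non-finite coordinates or values")
    return lon, lat, val


def idw_interpolate(stations, grid: GridSpec, config: IdwConfig | None = None) -> RasterGrid:
    """Interpolate station values onto every cell center of ``grid``.

    Each cell gets sum(w_i Z_i) / sum(w_i) with w_i = d_i^(-power); a cell
    within ``snap_tolerance`` of a station receives that station's value
    exactly. With ``max_stations`` set, only the k nearest stations enter
    the sum. Coincident stations (within snap tolerance of each other) with
    conflicting values are rejected; exact duplicates are merged.
    """
    config = config or IdwConfig()
    lon, lat, val = _station_arrays(stations)

    # reject/merge coincident stations
    keep = np.ones(lon.size, dtype=bool)
    for i in range(lon.size):
        if not keep[i]:
            continue
        for j in range(i + 1, lon.size):
            if keep[j] and np.hypot(lon[i] - lon[j], lat[i] - lat[j]) <= config.snap_tolerance:
                if val[i] != val[j]:
                    raise InvalidArgumentError(
                        f"coincident stations {i} and {j} with conflicting values"
                    )
                keep[j] = False
    lon, lat, val = lon[keep], lat[keep], val[keep]

    glon, glat = grid.cell_centers()
    pts = np.column_stack([glon.ravel(), glat.ravel()])  # (ncells, 2)
    d = np.hypot(pts[:, 0:1] - lon[None, :], pts[:, 1:2] - lat[None, :])  # (ncells, nstat)

    if config.max_stations is not None and config.max_stations < lon.size:
        k = config.max_stations
        order = np.argpartition(d, k - 1, axis=1)
        mask = np.ones_like(d, dtype=bool)
        rows = np.arange(d.shape[0])[:, None]
        mask[rows, order[:, :k]] = False
        d = np.where(mask, np.inf, d)

    snapped = d <= config.snap_tolerance
    with np.errstate(divide="ignore", over="ignore"):
        w = d ** (-config.power)
    w[~np.isfinite(w)] = 0.0  # snapped cells handled exactly below
    denom = w.sum(axis=1)
    denom[denom == 0] = np.nan
    out = (w * val[None, :]).sum(axis=1) / denom

    snap_rows, snap_cols = np.nonzero(snapped)
    out[snap_rows] = val[snap_cols]

    return RasterGrid(grid, out.reshape(grid.n_rows, grid.n_cols))


def zonal_mean(raster: RasterGrid, polygons: Mapping[str, Polygon]) -> pd.DataFrame:
    """Mean raster value per polygon over cell centers inside it.

    Boundary cells are assigned by a strict center-in-polygon test; nodata
    cells are excluded. A polygon capturing no cell center raises
    :class:`EmptyZoneError` naming the district.
    """
    if not polygons:
        raise InvalidArgumentError("no polygons supplied")
    glon, glat = raster.spec.cell_centers()
    x = glon.ravel()
    y = glat.ravel()
    v = raster.values.ravel()
    valid = v != raster.nodata
    rows = []
    for district_id, poly in polygons.items():
        inside = contains_xy(poly, x, y) & valid
        if not inside.any():
            raise EmptyZoneError(
                f"polygon {district_id} contains no valid cell center",
                district_id=district_id,
            )
        rows.append({"district_id": district_id, "value": float(v[inside].mean())})
    return pd.DataFrame(rows)
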