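"""Text-format readers and writers for rasters, points and polygons.

Rasters travel as Esri ASCII grids (``.asc``) — a plain-text format every
GIS reads — vector data as GeoJSON, and tables as CSV. All geometries are
in the package's planar meter CRS.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grids import DistrictMap, GridSpec, StationSet

NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray, nodata: float = NODATA) -> None:
    """Write a raster as an Esri ASCII grid (cell-corner registration)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values do not match grid shape")
    out = np.where(np.isfinite(values), values, nodata)
    x0, y0, _, _ = grid.extent
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {y0:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an Esri ASCII grid back into (GridSpec, values with NaN nodata)."""
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(hdr["nrows"]), int(hdr["ncols"])
    cell = hdr["cellsize"]
    grid = GridSpec(hdr["xllcorner"], hdr["yllcorner"] + n_rows * cell, cell, n_rows, n_cols)
    values = values.reshape(grid.shape)
    values[values == hdr["nodata_value"]] = np.nan
    return grid, values


def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def write_geojson(path: str | Path, features: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def stations_to_geojson(path: str | Path, stations: StationSet) -> None:
    from shapely.geometry import Point

    feats = [
        _feature(Point(x, y), {"station_id": int(i), "district": int(d)})
        for i, x, y, d in zip(stations.ids, stations.x, stations.y, stations.district)
    ]
    write_geojson(path, feats)


def region_to_polygon(grid: GridSpec, mask: np.ndarray):
    """Union of the cell squares of a boolean region (export convenience)."""
    half = grid.cell_size / 2.0
    xx, yy = grid.cell_centers()
    boxes = [
        box(x - half, y - half, x + half, y + half)
        for x, y in zip(xx[mask], yy[mask])
    ]
    return unary_union(boxes) if boxes else None


def districts_to_geojson(path: str | Path, districts: DistrictMap, grid: GridSpec) -> None:
    labels = districts.labels(grid)
    feats = []
    for d in districts.district_ids:
        poly = region_to_polygon(grid, labels == d)
        feats.append(
            _feature(poly, {"district": int(d), "group": int(districts.group_of[int(d)])})
        )
    write_geojson(path, feats)


def isochrones_to_geojson(path: str | Path, grid: GridSpec, thresholds, regions, period: str) -> None:
    feats = []
    for t, region in zip(thresholds, regions):
        poly = region_to_polygon(grid, region)
        if poly is not None and not poly.is_empty:
            feats.append(_feature(poly, {"period": period, "threshold_minutes": float(t)}))
    write_geojson(path, feats)
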