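"""Per-station isochrones within a sampling radius and their overlap map.

Each station, taken alone, covers the cells it can reach within a 12- or
15-minute response time; destinations are sampled only within a planar
radius of the station (8 km by default, wide enough to contain a 15-min
free-flow isochrone). Counting, per cell, how many stations cover it
exposes where station spacing is too dense (wasteful overlap) or too
sparse. Counts are binned into the four conventional classes: minimal
(<= 2), moderate (2-5], heavy (5-10] and extreme (10-20] overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import GridSpec

OVERLAP_CLASSES = [
    (0, 2, "minimal"),
    (2, 5, "moderate"),
    (5, 10, "heavy"),
    (10, 20, "extreme"),
]


@dataclass
class StationIsochrone:
    station_id: int
    period: str
    threshold_minutes: float
    grid: GridSpec
    covered: np.ndarray  # boolean, shape = grid.shape


@dataclass
class OverlapRaster:
    grid: GridSpec
    period: str
    threshold_minutes: float
    counts: np.ndarray  # integer station counts per cell
    classes: np.ndarray  # class label per cell ("" where count is 0)


def station_isochrone(
    station_id: int,
    station_xy: tuple[float, float],
    grid: GridSpec,
    driving_minutes: np.ndarray,
    dispatch_minutes: float,
    threshold_minutes: float,
    radius_m: float = 8000.0,
    period: str = "",
) -> StationIsochrone:
    """Cells this one station covers within the sampling radius.

    ``driving_minutes`` holds the station-to-cell driving time per flat
    cell (NaN = not sampled; inf = unreachable). A cell is covered when it
    lies within ``radius_m`` of the station and driving + dispatch <=
    threshold. NaN times inside the radius are an error — the sampling
    radius is supposed to be fully covered.
    """
    if radius_m <= 0:
        raise ValueError("radius must be > 0")
    t = np.asarray(driving_minutes, dtype=float).reshape(grid.shape)
    xx, yy = grid.cell_centers()
    in_radius = np.hypot(xx - station_xy[0], yy - station_xy[1]) <= radius_m
    missing = in_radius & np.isnan(t)
    if missing.any():
        raise ValueError(
            f"station {station_id}: {int(missing.sum())} cells inside the "
            f"{radius_m/1000:g} km radius have no travel time"
        )
    with np.errstate(invalid="ignore"):
        covered = in_radius & (t + dispatch_minutes <= threshold_minutes)
    return StationIsochrone(station_id, period, threshold_minutes, grid, covered)


def classify_counts(counts: np.ndarray) -> np.ndarray:
    """Map overlap counts onto the four frequency classes."""
    out = np.full(counts.shape, "", dtype=object)
    for lo, hi, name in OVERLAP_CLASSES:
        out[(counts > lo) & (counts <= hi)] = name
    over = counts > OVERLAP_CLASSES[-1][1]
    if over.any():
        warnings.warn(
            f"{int(over.sum())} cells exceed an overlap count of "
            f"{OVERLAP_CLASSES[-1][1]}; mapped to the top class"
        )
        out[over] = OVERLAP_CLASSES[-1][2]
    # counts in (0, lo] of the first class (i.e. 1..2) fall in "minimal"
    out[(counts > 0) & (counts <= OVERLAP_CLASSES[0][1])] = OVERLAP_CLASSES[0][2]
    return out


def overlap_frequency(isochrones: Sequence[StationIsochrone], grid: GridSpec) -> OverlapRaster:
    """Per-cell count of stations whose isochrone covers the cell."""
    if not isochrones:
        raise ValueError("need at least one station isochrone")
    periods = {iso.period for iso in isochrones}
    thresholds = {iso.threshold_minutes for iso in isochrones}
    if len(periods) > 1 or len(thresholds) > 1:
        raise ValueError(
            f"isochrones mix periods {sorted(periods)} / thresholds {sorted(thresholds)}; "
            "overlap is defined per (period, threshold)"
        )
    for iso in isochrones:
        if not iso.grid.same_geometry(grid):
            raise ValueError("all isochrones must share the target grid")
    counts = np.zeros(grid.shape, dtype=int)
    for iso in isochrones:
        counts += iso.covered.astype(int)
    return OverlapRaster(
        grid, isochrones[0].period, isochrones[0].threshold_minutes, counts, classify_counts(counts)
    )
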