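"""Planar raster grids and the domain containers shared by every stage.

All grids live in one projected CRS with coordinates in meters. Row 0 is
the north edge and a cell's value refers to its center; these conventions
are fixed so that repeated runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised for invalid grid, city or run configuration."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an axis-aligned raster: origin is the north-west corner.

    Parameters
    ----------
    origin_x, origin_y:
        Planar coordinates (m) of the north-west corner of cell (0, 0).
    cell_size:
        Edge length of a square cell in meters.
    n_rows, n_cols:
        Raster dimensions.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError(
                f"grid must have at least one cell, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the raster footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as (x, y) arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_centers_flat(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, row-major order."""
        xx, yy = self.cell_centers()
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_of_point(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if outside."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        # points exactly on the south/east boundary snap inward
        if col == self.n_cols and np.isclose(x, self.extent[2]):
            col -= 1
        if row == self.n_rows and np.isclose(y, self.extent[1]):
            row -= 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) lies outside the grid extent {self.extent}")
        return row, col

    def flat_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
            and self.shape == other.shape
        )


def _check_grid_values(grid: GridSpec, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"{name} shape {values.shape} does not match grid {grid.shape}")
    return values


@dataclass
class PopulationGrid:
    """People per cell on a :class:`GridSpec`; an extensive quantity."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_grid_values(self.grid, self.values, "population")
        if np.any(self.values < 0):
            raise ValueError("population values must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class SpeedField:
    """Per-cell driving speed (m/min) for one traffic period."""

    period: str
    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_grid_values(self.grid, self.values, "speed")
        if np.any(self.values <= 0):
            raise ValueError("speeds must be strictly positive everywhere")


@dataclass
class StationSet:
    """EMS station origins: id, planar coordinates and district label."""

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    district: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.district = np.asarray(self.district, dtype=int)
        n = len(self.ids)
        if not (len(self.x) == len(self.y) == len(self.district) == n):
            raise ValueError("station columns must have equal length")
        if len(np.unique(self.ids)) != n:
            raise ValueError("station ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"station_id": self.ids, "x": self.x, "y": self.y, "district": self.district}
        )

    def sorted_by_id(self) -> "StationSet":
        order = np.argsort(self.ids, kind="stable")
        return StationSet(self.ids[order], self.x[order], self.y[order], self.district[order])


@dataclass
class DistrictMap:
    """Voronoi district partition from seed points, with a central/suburban split.

    Districts are the nearest-seed cells of ``seed_xy``; ``group_of`` maps each
    district id to group 1 (central) or group 2 (suburban). Labels can be
    rasterized onto any grid so the 250 m analysis grid and the 100 m output
    grid stay consistent.
    """

    district_ids: np.ndarray
    seed_xy: np.ndarray
    group_of: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.district_ids = np.asarray(self.district_ids, dtype=int)
        self.seed_xy = np.asarray(self.seed_xy, dtype=float)
        if self.seed_xy.shape != (len(self.district_ids), 2):
            raise ValueError("seed_xy must be (n_districts, 2)")
        missing = [d for d in self.district_ids if d not in self.group_of]
        if missing:
            raise ValueError(f"districts without a group assignment: {missing}")
        bad = {d: g for d, g in self.group_of.items() if g not in (1, 2)}
        if bad:
            raise ValueError(f"groups must be 1 (central) or 2 (suburban), got {bad}")

    def labels(self, grid: GridSpec) -> np.ndarray:
        """District id per cell of ``grid`` (nearest seed; ties to lower id)."""
        centers = grid.cell_centers_flat()
        d2 = ((centers[:, None, :] - self.seed_xy[None, :, :]) ** 2).sum(axis=2)
        order = np.argsort(self.district_ids, kind="stable")
        nearest = np.argmin(d2[:, order], axis=1)
        return self.district_ids[order][nearest].reshape(grid.shape)

    def groups(self, grid: GridSpec) -> np.ndarray:
        """Group (1 or 2) per cell of ``grid``."""
        lab = self.labels(grid)
        out = np.zeros_like(lab)
        for d, g in self.group_of.items():
            out[lab == d] = g
        return out


def resample_weights(src: GridSpec, dst: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """1-D area-overlap weight matrices (rows, cols) mapping src cells to dst.

    Entry (i, j) is the fraction of src interval j that overlaps dst interval
    i, so ``Wr @ V @ Wc.T`` redistributes an extensive quantity (people)
    conservatively as long as dst covers src.
    """

    def axis_weights(o_src: float, n_src: int, o_dst: float, n_dst: int, sgn: float) -> np.ndarray:
        # sgn=+1 for x (increasing), -1 for y (row 0 at north, decreasing y)
        s_edges = o_src + sgn * src.cell_size * np.arange(n_src + 1)
        d_edges = o_dst + sgn * dst.cell_size * np.arange(n_dst + 1)
        if sgn < 0:
            s_edges, d_edges = -s_edges, -d_edges
        w = np.zeros((n_dst, n_src))
        for i in range(n_dst):
            lo = np.maximum(d_edges[i], s_edges[:-1])
            hi = np.minimum(d_edges[i + 1], s_edges[1:])
            w[i] = np.clip(hi - lo, 0.0, None) / src.cell_size
        return w

    wr = axis_weights(src.origin_y, src.n_rows, dst.origin_y, dst.n_rows, -1.0)
    wc = axis_weights(src.origin_x, src.n_cols, dst.origin_x, dst.n_cols, +1.0)
    return wr, wc


def resample_population(pop: PopulationGrid, out_grid: GridSpec) -> PopulationGrid:
    """Area-weighted redistribution of population onto ``out_grid``.

    People are extensive, so mass within the shared extent is conserved
    (relative error at floating-point level). Raises if the extents are
    disjoint.
    """
    sx0, sy0, sx1, sy1 = pop.grid.extent
    dx0, dy0, dx1, dy1 = out_grid.extent
    if sx1 <= dx0 or dx1 <= sx0 or sy1 <= dy0 or dy1 <= sy0:
        raise ValueError("population grid and output grid extents are disjoint")
    wr, wc = resample_weights(pop.grid, out_grid)
    out = wr @ pop.values @ wc.T
    # clamp tiny negative round-off
    out[out < 0] = 0.0
    return PopulationGrid(out_grid, out)
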