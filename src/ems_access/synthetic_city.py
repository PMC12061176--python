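"""Synthetic city generator and travel-time oracle.

Real studies of ambulance accessibility draw on a gridded population
product, the locations of EMS stations, district boundaries with a
central/suburban classification, and driving times sampled from a
web-mapping route-planning service at several times of day. None of those
can ship with a library, so this module builds a self-contained stand-in:

* a population surface that decays exponentially from one or two urban
  cores with multiplicative lognormal noise, so a dense center and sparse
  periphery exist by construction;
* Voronoi districts from seed points, the seeds nearest the city center
  forming group 1 (central) and the rest group 2 (suburban);
* stations placed preferentially where people are;
* one speed field (m/min) per traffic period, a smooth core-slow /
  periphery-fast surface scaled down by a per-period congestion
  multiplier;
* a shortest-path travel-time oracle over the 8-connected grid graph that
  plays the role of the routing API and serves as ground truth for the
  downstream validation.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._graph import shortest_costs
from .grids import (
    ConfigurationError,
    DistrictMap,
    GridSpec,
    PopulationGrid,
    SpeedField,
    StationSet,
)

DEFAULT_PERIODS = {"00:00": 1.0, "12:00": 0.85, "16:00": 0.75, "18:00": 0.65}


class UnreachableError(RuntimeError):
    """A destination cell cannot be reached from the origin."""


@dataclass
class CityConfig:
    """Parameters of the synthetic city.

    Defaults describe a mid-sized 12.5 km x 12.5 km city on the 250 m
    analysis grid: 20 stations clustered where people are, 8 districts
    (3 central), 1.2 M inhabitants,
    effective door-to-scene ambulance speeds from 200 m/min (12 km/h) in
    the congested core to 400 m/min (24 km/h) at the periphery, and four traffic periods
    whose multipliers scale all speeds down toward the evening peak.
    """

    seed: int = 1
    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 250.0
    n_stations: int = 20
    n_districts: int = 8
    n_central_districts: int = 3
    total_population: float = 1_200_000.0
    # two-component exponential decay: (weight, decay range as a fraction of extent)
    pop_components: tuple[tuple[float, float], ...] = ((0.6, 0.15), (0.4, 0.6))
    pop_noise_sigma: float = 0.3
    second_core_offset: tuple[float, float] = (0.18, 0.12)  # fraction of extent
    v_core: float = 200.0
    v_periphery: float = 400.0
    speed_sigma_frac: float = 0.25
    congestion: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PERIODS))
    station_density_power: float = 2.0

    def validate(self) -> None:
        if self.n_stations < 1:
            raise ConfigurationError("n_stations must be >= 1")
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.n_districts < 1 or not (0 <= self.n_central_districts <= self.n_districts):
            raise ConfigurationError("invalid district configuration")
        if any(m <= 0 for m in self.congestion.values()):
            raise ConfigurationError("congestion multipliers must be > 0")
        if self.v_core <= 0 or self.v_periphery <= 0:
            raise ConfigurationError("speeds must be > 0")
        if self.total_population <= 0:
            raise ConfigurationError("total_population must be > 0")


@dataclass
class City:
    """A generated city: all inputs the downstream analysis needs."""

    config: CityConfig
    grid: GridSpec
    population: PopulationGrid
    districts: DistrictMap
    stations: StationSet
    speeds: list[SpeedField]

    def speed_for(self, period: str) -> SpeedField:
        for s in self.speeds:
            if s.period == period:
                return s
        raise KeyError(f"no speed field for period {period!r}")

    @property
    def periods(self) -> list[str]:
        return [s.period for s in self.speeds]


def _population_surface(cfg: CityConfig, grid: GridSpec, rng: np.random.Generator) -> np.ndarray:
    xx, yy = grid.cell_centers()
    x0, y0, x1, y1 = grid.extent
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    extent = max(x1 - x0, y1 - y0)
    centers = [(cx, cy), (cx + cfg.second_core_offset[0] * extent, cy + cfg.second_core_offset[1] * extent)]
    base = np.zeros(grid.shape)
    for (w, r_frac), (px, py) in zip(cfg.pop_components, centers):
        d = np.hypot(xx - px, yy - py)
        base += w * np.exp(-d / (r_frac * extent))
    noise = rng.lognormal(mean=0.0, sigma=cfg.pop_noise_sigma, size=grid.shape)
    vals = base * noise
    return vals * (cfg.total_population / vals.sum())


def _speed_surface(cfg: CityConfig, grid: GridSpec) -> np.ndarray:
    """Free-flow speed: slow in the dense core, fast at the periphery."""
    xx, yy = grid.cell_centers()
    x0, y0, x1, y1 = grid.extent
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    extent = max(x1 - x0, y1 - y0)
    d = np.hypot(xx - cx, yy - cy)
    sigma = cfg.speed_sigma_frac * extent
    return cfg.v_periphery - (cfg.v_periphery - cfg.v_core) * np.exp(-0.5 * (d / sigma) ** 2)


def _sample_cells_weighted(
    rng: np.random.Generator, weights: np.ndarray, n: int
) -> np.ndarray:
    """Distinct flat cell indices drawn with probability proportional to weights."""
    p = weights.ravel().astype(float)
    p = p / p.sum()
    if n > np.count_nonzero(p):
        raise ConfigurationError(f"cannot place {n} points on {np.count_nonzero(p)} weighted cells")
    return rng.choice(p.size, size=n, replace=False, p=p)


def generate_city(cfg: CityConfig | None = None, **overrides) -> City:
    """Build the full synthetic city for a :class:`CityConfig`.

    Keyword overrides are applied on top of ``cfg`` (or the defaults), e.g.
    ``generate_city(seed=7, n_stations=4)``.
    """
    if cfg is None:
        cfg = CityConfig()
    if overrides:
        cfg = CityConfig(**{**cfg.__dict__, **overrides})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    grid = GridSpec(0.0, cfg.n_rows * cfg.cell_size, cfg.cell_size, cfg.n_rows, cfg.n_cols)

    pop = PopulationGrid(grid, _population_surface(cfg, grid, rng))

    # districts: weighted seed placement, group 1 = seeds nearest the center
    seed_cells = _sample_cells_weighted(rng, np.ones(grid.shape), cfg.n_districts)
    seed_xy = grid.cell_centers_flat()[seed_cells]
    district_ids = np.arange(1, cfg.n_districts + 1)
    x0, y0, x1, y1 = grid.extent
    center = np.array([(x0 + x1) / 2, (y0 + y1) / 2])
    d_center = np.hypot(*(seed_xy - center).T)
    central = set(district_ids[np.argsort(d_center, kind="stable")[: cfg.n_central_districts]])
    group_of = {int(d): (1 if d in central else 2) for d in district_ids}
    districts = DistrictMap(district_ids, seed_xy, group_of)

    # stations follow population density; a power > 1 concentrates them in
    # the core, reproducing the center-heavy station layouts of real cities
    station_cells = _sample_cells_weighted(
        rng, pop.values**cfg.station_density_power, cfg.n_stations
    )
    station_xy = grid.cell_centers_flat()[station_cells]
    labels = districts.labels(grid).ravel()
    stations = StationSet(
        ids=np.arange(1, cfg.n_stations + 1),
        x=station_xy[:, 0],
        y=station_xy[:, 1],
        district=labels[station_cells],
    )

    base_speed = _speed_surface(cfg, grid)
    speeds = [
        SpeedField(period, grid, base_speed * mult) for period, mult in cfg.congestion.items()
    ]
    return City(cfg, grid, pop, districts, stations, speeds)


def travel_time_matrix(stations: StationSet, speed: SpeedField, connectivity: int = 8) -> np.ndarray:
    """Least-time driving minutes from every station to every cell.

    Shape (n_stations, n_cells) in the station order of ``stations`` and
    row-major flat cell order; ``inf`` marks unreachable cells.
    """
    grid = speed.grid
    cells = np.array(
        [grid.flat_index(*grid.cell_of_point(x, y)) for x, y in stations.xy], dtype=int
    )
    rate = 1.0 / speed.values  # minutes per meter
    return shortest_costs(rate, grid.cell_size, cells, connectivity=connectivity)


def oracle_travel_time(
    origin: StationSet | tuple[float, float],
    dest_cell: tuple[int, int] | int,
    speed: SpeedField,
    connectivity: int = 8,
) -> float:
    """Driving minutes from one origin to one destination cell.

    ``origin`` is a single-station :class:`StationSet` or an (x, y) pair;
    ``dest_cell`` a (row, col) pair or a flat index. Raises
    :class:`UnreachableError` rather than returning a silent sentinel when
    no path exists.
    """
    grid = speed.grid
    if isinstance(origin, StationSet):
        if len(origin) != 1:
            raise ValueError("origin must be a single station")
        ox, oy = float(origin.x[0]), float(origin.y[0])
    else:
        ox, oy = origin
    src = grid.flat_index(*grid.cell_of_point(ox, oy))
    if isinstance(dest_cell, tuple):
        dest = grid.flat_index(*dest_cell)
    else:
        dest = int(dest_cell)
    if not (0 <= dest < grid.n_cells):
        raise ValueError(f"destination cell {dest_cell} outside grid")
    rate = 1.0 / speed.values
    t = shortest_costs(rate, grid.cell_size, np.array([src]), connectivity=connectivity)[0, dest]
    if not np.isfinite(t):
        raise UnreachableError(f"cell {dest_cell} unreachable from origin ({ox}, {oy})")
    return float(t)
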