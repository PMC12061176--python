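"""End-to-end orchestration: city -> times -> surfaces -> all indicators.

``run_all`` executes the whole multi-scale analysis on a (synthetic) city
and returns every intermediate and final product; given an output
directory it also writes the standard artifact set (resolved config,
rasters as ASCII grids, vectors as GeoJSON, tables as CSV, a summary and
a checksum manifest) so runs are auditable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .access_surface import (
    AccessSurface,
    InterpConfig,
    focal_clean,
    interpolate_surface,
    mask_populated,
)
from .equity import equity_report
from .grids import GridSpec, PopulationGrid, SpeedField, resample_population
from .indicators import (
    IsochroneSet,
    build_isochrones,
    compute_prt,
    coverage_rates,
    prt_change_table,
)
from .overlap import overlap_frequency, station_isochrone
from .partition import (
    DEFAULT_TEAMS_PER_CAPITA,
    compare_partition_models,
    impedance_from_surface,
    mcr_allocate,
    station_stats,
)
from .synthetic_city import City, CityConfig, generate_city, travel_time_matrix
from .travel_time import build_response_field, sample_travel_times

log = logging.getLogger("ems_access")


@dataclass
class RunConfig:
    """All knobs of a full run; defaults follow the standard study design.

    Destinations on a 250 m grid matched to their k = 3 nearest stations,
    a 2-minute dispatch offset, a 100 m output surface, 9/12/15-minute
    coverage thresholds, 12/15-minute per-station isochrones within an
    8 km sampling radius, and one ambulance team per 30,000 people.
    """

    city: CityConfig = field(default_factory=CityConfig)
    out_cell_size: float = 100.0
    k: int = 3
    dispatch_minutes: float = 2.0
    isochrone_interval: float = 1.0
    coverage_thresholds: tuple[float, ...] = (9.0, 12.0, 15.0)
    overlap_thresholds: tuple[float, ...] = (12.0, 15.0)
    overlap_radius_m: float = 8000.0
    teams_per_capita: float = DEFAULT_TEAMS_PER_CAPITA
    interp: InterpConfig = field(default_factory=InterpConfig)
    focal_window: int = 3
    focal_z_thresh: float = 3.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "city" in d and isinstance(d["city"], dict):
            c = dict(d["city"])
            # YAML round-trips tuples as lists; restore the frozen types
            if "pop_components" in c:
                c["pop_components"] = tuple(tuple(p) for p in c["pop_components"])
            if "second_core_offset" in c:
                c["second_core_offset"] = tuple(c["second_core_offset"])
            d["city"] = CityConfig(**c)
        if "interp" in d and isinstance(d["interp"], dict):
            d["interp"] = InterpConfig(**d["interp"])
        for key in ("coverage_thresholds", "overlap_thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunResult:
    config: RunConfig
    city: City
    out_grid: GridSpec
    pop_fine: PopulationGrid
    surfaces: dict[str, AccessSurface]
    isochrones: dict[str, IsochroneSet]
    od: pd.DataFrame  # travel-time cache (station_id, cell_id, period, driving_minutes)
    prt: pd.DataFrame  # scope, period, prt_minutes, population
    coverage: pd.DataFrame
    prt_changes: pd.DataFrame
    theil: pd.DataFrame
    stations: pd.DataFrame  # per-station stats, all periods
    comparison: dict  # period -> model comparison report
    overlaps: dict[tuple[str, float], object]
    fine_oracle_minutes: dict[str, np.ndarray]  # per-cell truth, fine grid
    fine_time_matrices: dict[str, np.ndarray]

    def summary(self) -> dict:
        city_prt = self.prt[self.prt["scope"] == "city"]
        cov_city = self.coverage[self.coverage["scope"] == "city"]
        return {
            "periods": list(self.surfaces),
            "total_population": self.city.population.total,
            "n_stations": len(self.city.stations),
            "city_prt_minutes": {
                r.period: r.prt_minutes for r in city_prt.itertuples()
            },
            "coverage_rates": {
                f"{r.period}@{r.threshold_minutes:g}min": r.coverage_rate
                for r in cov_city.itertuples()
                if r.threshold_minutes in self.config.coverage_thresholds
            },
            "theil": self.theil.to_dict(orient="records"),
            "model_comparison": self.comparison,
            "max_station_demand_teams": float(self.stations["demand_teams"].max()),
        }


def _fine_grid(base: GridSpec, out_cell: float) -> GridSpec:
    width = base.n_cols * base.cell_size
    height = base.n_rows * base.cell_size
    return GridSpec(
        base.origin_x,
        base.origin_y,
        out_cell,
        int(round(height / out_cell)),
        int(round(width / out_cell)),
    )


def _point_sample(src: GridSpec, values: np.ndarray, dst: GridSpec) -> np.ndarray:
    """Nearest (containing-cell) sampling of an intensive raster onto dst."""
    xx, yy = dst.cell_centers()
    cols = np.clip(((xx - src.origin_x) / src.cell_size).astype(int), 0, src.n_cols - 1)
    rows = np.clip(((src.origin_y - yy) / src.cell_size).astype(int), 0, src.n_rows - 1)
    return values[rows, cols]


def run_all(config: RunConfig | None = None, out_dir: str | Path | None = None) -> RunResult:
    """Run the complete analysis; optionally write the artifact set."""
    config = config or RunConfig()
    cfg = config

    log.info("stage city: generating synthetic city (seed=%d)", cfg.city.seed)
    city = generate_city(cfg.city)
    periods = city.periods

    log.info("stage travel_time: oracle matrices + k=%d OD sampling", cfg.k)
    coarse_tm = {p: travel_time_matrix(city.stations.sorted_by_id(), city.speed_for(p)) for p in periods}
    od = sample_travel_times(city, k=cfg.k, time_matrices=coarse_tm)
    field_ = build_response_field(od, city.grid, cfg.dispatch_minutes, periods)

    out_grid = _fine_grid(city.grid, cfg.out_cell_size)
    pop_fine = resample_population(city.population, out_grid)

    # fine-grid ground truth (oracle on resampled speed fields), reused by
    # the partition comparison and the overlap stage
    st = city.stations.sorted_by_id()
    fine_tm: dict[str, np.ndarray] = {}
    fine_oracle: dict[str, np.ndarray] = {}
    for p in periods:
        fine_speed = SpeedField(p, out_grid, _point_sample(city.grid, city.speed_for(p).values, out_grid))
        fine_tm[p] = travel_time_matrix(st, fine_speed)
        fine_oracle[p] = fine_tm[p].min(axis=0)

    surfaces: dict[str, AccessSurface] = {}
    isochrones: dict[str, IsochroneSet] = {}
    prt_rows: list = []
    cov_frames: list = []
    station_frames: list = []
    comparison: dict = {}
    overlaps: dict = {}

    district_labels = city.districts.labels(out_grid)
    district_ids = [int(d) for d in city.districts.district_ids]
    scopes = {"city": np.ones(out_grid.shape, dtype=bool)}
    scopes.update({str(d): district_labels == d for d in district_ids})

    for p in periods:
        log.info("stage surface: period %s", p)
        surf = interpolate_surface(field_, out_grid, p, cfg.interp, seed=cfg.city.seed)
        surf = focal_clean(surf, cfg.focal_window, cfg.focal_z_thresh)
        surf = mask_populated(surf, city.population)
        surfaces[p] = surf

        log.info("stage indicators: period %s", p)
        iso_top = max(
            float(np.nanmax(surf.valid_values())), max(cfg.coverage_thresholds)
        )
        iso = build_isochrones(surf, cfg.isochrone_interval, max_minutes=iso_top)
        isochrones[p] = iso
        for name, mask in scopes.items():
            r = compute_prt(surf, pop_fine, mask, scope=name)
            prt_rows.append(
                {"scope": name, "period": p, "prt_minutes": r.prt_minutes, "population": r.population}
            )
        cov_frames.append(
            coverage_rates(iso, pop_fine, scopes, thresholds=list(cfg.coverage_thresholds))
        )

        log.info("stage partition: period %s", p)
        imp = impedance_from_surface(surf)
        part = mcr_allocate(imp, city.stations)
        station_frames.append(
            station_stats(part, pop_fine, surf, cfg.teams_per_capita)
        )
        comparison[p] = compare_partition_models(imp, city.stations, fine_oracle[p])

        log.info("stage overlap: period %s", p)
        for thr in cfg.overlap_thresholds:
            isos = [
                station_isochrone(
                    int(sid),
                    (float(x), float(y)),
                    out_grid,
                    fine_tm[p][i],
                    cfg.dispatch_minutes,
                    thr,
                    cfg.overlap_radius_m,
                    period=p,
                )
                for i, (sid, x, y) in enumerate(zip(st.ids, st.x, st.y))
            ]
            overlaps[(p, thr)] = overlap_frequency(isos, out_grid)

    prt = pd.DataFrame(prt_rows)
    coverage = pd.concat(cov_frames, ignore_index=True)
    stations_df = pd.concat(station_frames, ignore_index=True)
    changes = prt_change_table(prt, periods[0], periods[-1]) if len(periods) > 1 else pd.DataFrame()

    log.info("stage equity: Theil decompositions")
    district_groups = pd.DataFrame(
        {
            "district": [str(d) for d in district_ids],
            "group": [city.districts.group_of[d] for d in district_ids],
        }
    )
    dist_prt = prt[prt["scope"] != "city"]
    dist_cov = coverage[coverage["scope"] != "city"]
    theil = equity_report(dist_prt, dist_cov, district_groups)

    result = RunResult(
        cfg, city, out_grid, pop_fine, surfaces, isochrones, od, prt, coverage,
        changes, theil, stations_df, comparison, overlaps, fine_oracle, fine_tm,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(res: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(path: Path) -> Path:
        written.append(path)
        return path

    with open(save(out_dir / "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(res.config.to_dict(), fh, sort_keys=True)

    city_dir = out_dir / "city"
    city_dir.mkdir(exist_ok=True)
    eio.write_ascii_grid(save(city_dir / "population.asc"), res.city.grid, res.city.population.values)
    for s in res.city.speeds:
        eio.write_ascii_grid(save(city_dir / f"speed_{s.period.replace(':', '')}.asc"), s.grid, s.values)
    eio.stations_to_geojson(save(city_dir / "stations.geojson"), res.city.stations)
    eio.districts_to_geojson(save(city_dir / "districts.geojson"), res.city.districts, res.city.grid)

    surf_dir = out_dir / "surfaces"
    surf_dir.mkdir(exist_ok=True)
    for p, surf in res.surfaces.items():
        vals = np.where(surf.mask, surf.values, np.nan)
        eio.write_ascii_grid(save(surf_dir / f"access_{p.replace(':', '')}.asc"), surf.grid, vals)
        iso = res.isochrones[p]
        eio.isochrones_to_geojson(
            save(surf_dir / f"isochrones_{p.replace(':', '')}.geojson"),
            surf.grid, iso.thresholds, iso.regions, p,
        )

    res.od.to_csv(save(out_dir / "travel_times.csv"), index=False)
    res.prt.to_csv(save(out_dir / "prt.csv"), index=False)
    res.coverage.to_csv(save(out_dir / "coverage.csv"), index=False)
    if len(res.prt_changes):
        res.prt_changes.to_csv(save(out_dir / "prt_changes.csv"), index=False)
    res.theil.to_csv(save(out_dir / "theil.csv"), index=False)
    res.stations.to_csv(save(out_dir / "station_stats.csv"), index=False)
    with open(save(out_dir / "model_comparison.json"), "w") as fh:
        json.dump(res.comparison, fh, indent=1)

    ov_dir = out_dir / "overlap"
    ov_dir.mkdir(exist_ok=True)
    for (p, thr), ov in res.overlaps.items():
        eio.write_ascii_grid(
            save(ov_dir / f"overlap_{p.replace(':', '')}_{thr:g}min.asc"),
            ov.grid, ov.counts.astype(float),
        )

    with open(save(out_dir / "summary.json"), "w") as fh:
        json.dump(res.summary(), fh, indent=1)

    manifest = {
        str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in written
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
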