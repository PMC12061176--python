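"""Accessibility indicators: per-capita response time and isochrone coverage.

The per-capita response time (PRT) of a scope is the population-weighted
mean response time

    Rbar = sum_i P_i R_i / sum_i P_i

over the valid, populated cells of the scope. Accessibility isochrones
(EAIs) are the nested regions with response time at or below a threshold;
the coverage rate of an EAI is the share of a scope's population inside
it. Both statistics are computed on the raster directly — polygons are an
export format only — and a cell counts as covered when R <= t (closed
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .access_surface import AccessSurface
from .grids import PopulationGrid


class EmptyScopeError(ValueError):
    """A scope holds no population; the weighted mean is undefined."""


@dataclass
class PRTResult:
    scope: str
    period: str
    prt_minutes: float
    population: float


@dataclass
class IsochroneSet:
    """Nested threshold regions of one surface: region(t) = {cells: R <= t}."""

    period: str
    thresholds: list[float]
    regions: list[np.ndarray]  # boolean masks, same shape as the surface

    def region(self, threshold: float) -> np.ndarray:
        for t, r in zip(self.thresholds, self.regions):
            if np.isclose(t, threshold):
                return r
        raise KeyError(f"no isochrone at threshold {threshold}")


def compute_prt(
    surface: AccessSurface,
    pop: PopulationGrid,
    scope_mask: np.ndarray | None = None,
    scope: str = "city",
) -> PRTResult:
    """Population-weighted mean response time over a scope."""
    if not pop.grid.same_geometry(surface.grid):
        raise ValueError("population grid must be co-registered with the surface")
    m = surface.mask if scope_mask is None else (surface.mask & scope_mask)
    weights = pop.values[m]
    total = weights.sum()
    if not total > 0:
        raise EmptyScopeError(f"scope {scope!r} has zero population")
    prt = float((weights * surface.values[m]).sum() / total)
    return PRTResult(scope, surface.period, prt, float(total))


def build_isochrones(
    surface: AccessSurface, interval_minutes: float = 1.0, max_minutes: float | None = None
) -> IsochroneSet:
    """Threshold the surface at interval, 2*interval, ... into nested regions."""
    if interval_minutes <= 0:
        raise ValueError("interval must be > 0")
    top = max_minutes if max_minutes is not None else float(np.nanmax(surface.valid_values()))
    n = int(np.ceil(top / interval_minutes))
    thresholds = [interval_minutes * (i + 1) for i in range(max(n, 1))]
    regions = [surface.mask & (surface.values <= t) for t in thresholds]
    return IsochroneSet(surface.period, thresholds, regions)


def coverage_rates(
    iso: IsochroneSet,
    pop: PopulationGrid,
    scopes: dict[str, np.ndarray] | None = None,
    thresholds: list[float] | None = None,
) -> pd.DataFrame:
    """Population share of each scope inside each isochrone.

    ``scopes`` maps scope names to boolean masks (default: one "city"
    scope covering everything); rows are (scope, period, threshold_minutes,
    coverage_rate) with rates in [0, 1].
    """
    scopes = scopes or {"city": np.ones(pop.values.shape, dtype=bool)}
    thresholds = thresholds or iso.thresholds
    rows = []
    for name, scope_mask in scopes.items():
        denom = pop.values[scope_mask].sum()
        if not denom > 0:
            raise EmptyScopeError(f"scope {name!r} has zero population")
        for t in thresholds:
            region = iso.region(t)
            num = pop.values[region & scope_mask].sum()
            rows.append(
                {
                    "scope": name,
                    "period": iso.period,
                    "threshold_minutes": t,
                    "coverage_rate": float(num / denom),
                }
            )
    return pd.DataFrame(rows)


def prt_change_table(
    prt_table: pd.DataFrame, baseline_period: str, comparison_period: str
) -> pd.DataFrame:
    """Relative PRT change between two periods, percent to one decimal.

    ``prt_table`` needs columns (scope, period, prt_minutes). The change is
    (late - early) / early * 100, matching how district-level congestion
    effects are usually reported.
    """
    for p in (baseline_period, comparison_period):
        if p not in set(prt_table["period"]):
            raise ValueError(f"period {p!r} missing from the PRT table")
    wide = prt_table.pivot_table(index="scope", columns="period", values="prt_minutes")
    if wide[baseline_period].isna().any() or wide[comparison_period].isna().any():
        missing = wide.index[wide[[baseline_period, comparison_period]].isna().any(axis=1)]
        raise ValueError(f"scopes missing a period: {list(missing)}")
    change = (wide[comparison_period] - wide[baseline_period]) / wide[baseline_period] * 100.0
    return pd.DataFrame(
        {
            "scope": wide.index,
            "prt_baseline": wide[baseline_period].to_numpy(),
            "prt_comparison": wide[comparison_period].to_numpy(),
            "change_pct": np.round(change.to_numpy(), 1),
        }
    ).reset_index(drop=True)
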