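"""Origin-destination matching and response-time fields.

Each demand cell (the 250 m analysis grid by default) is matched to its k
nearest stations by planar distance — mirroring a GIS near-table with
k = 3 — and the routing oracle is queried for each pair and traffic
period. The response time of a cell is the minimum driving time over its
matched stations plus a fixed dispatch offset (2 min by default, the time
from call to ambulance departure).

k-nearest matching is an approximation: the closest station by air
distance need not be closest by driving time. With k equal to the number
of stations the approximation vanishes, which the test suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSpec, StationSet
from .synthetic_city import City, travel_time_matrix

OD_COLUMNS = ["station_id", "cell_id", "period", "driving_minutes"]


@dataclass
class ResponseField:
    """Per-cell, per-period EMS response time on the analysis grid.

    ``values[period]`` is a flat (n_cells,) array of minutes, already
    including the dispatch offset.
    """

    grid: GridSpec
    dispatch_minutes: float
    values: dict[str, np.ndarray]

    @property
    def periods(self) -> list[str]:
        return list(self.values)

    def as_raster(self, period: str) -> np.ndarray:
        return self.values[period].reshape(self.grid.shape)


def match_k_nearest(dest_xy: np.ndarray, stations: StationSet, k: int) -> pd.DataFrame:
    """Pair every destination with its k nearest stations by planar distance.

    Returns a DataFrame with columns (cell_id, station_id, distance_m),
    ``cell_id`` being the row index into ``dest_xy``. Ties in distance are
    broken toward the lower station id, deterministically.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(stations):
        raise ValueError(f"k={k} exceeds the number of stations ({len(stations)})")
    dest_xy = np.asarray(dest_xy, dtype=float)
    st = stations.sorted_by_id()
    d = np.hypot(
        dest_xy[:, 0:1] - st.x[None, :], dest_xy[:, 1:2] - st.y[None, :]
    )  # (n_cells, n_stations)
    # stable argsort on distance with stations pre-sorted by id => lower id wins ties
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    n_cells = len(dest_xy)
    cell_ids = np.repeat(np.arange(n_cells), k)
    flat = order.ravel()
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "station_id": st.ids[flat],
            "distance_m": d[np.repeat(np.arange(n_cells), k), flat],
        }
    )


def sample_travel_times(
    city: City,
    k: int = 3,
    periods: list[str] | None = None,
    time_matrices: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """OD driving times for the k-nearest matching, all requested periods.

    Runs the city's shortest-path oracle for each station (the stand-in for
    a routing API call per OD pair) and returns tidy records with columns
    (station_id, cell_id, period, driving_minutes). Precomputed per-period
    time matrices may be supplied to avoid repeating the oracle runs.
    """
    periods = periods or city.periods
    od = match_k_nearest(city.grid.cell_centers_flat(), city.stations, k)
    st = city.stations.sorted_by_id()
    id_to_row = {int(sid): i for i, sid in enumerate(st.ids)}
    frames = []
    for period in periods:
        if time_matrices is not None and period in time_matrices:
            tm = time_matrices[period]
        else:
            tm = travel_time_matrix(st, city.speed_for(period))
        rows = np.array([id_to_row[s] for s in od["station_id"]])
        frames.append(
            pd.DataFrame(
                {
                    "station_id": od["station_id"].to_numpy(),
                    "cell_id": od["cell_id"].to_numpy(),
                    "period": period,
                    "driving_minutes": tm[rows, od["cell_id"].to_numpy()],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def build_response_field(
    od: pd.DataFrame,
    grid: GridSpec,
    dispatch_minutes: float = 2.0,
    periods: list[str] | None = None,
) -> ResponseField:
    """Reduce OD records to per-cell response times: min driving time + dispatch.

    Every cell must carry at least one OD record in every period; missing
    cells are reported explicitly rather than silently filled.
    """
    if dispatch_minutes < 0:
        raise ValueError("dispatch_minutes must be >= 0")
    if (od["driving_minutes"] < 0).any():
        raise ValueError("driving_minutes must be nonnegative")
    periods = periods or sorted(od["period"].unique())
    values: dict[str, np.ndarray] = {}
    for period in periods:
        sub = od[od["period"] == period]
        mins = sub.groupby("cell_id")["driving_minutes"].min()
        missing = np.setdiff1d(np.arange(grid.n_cells), mins.index.to_numpy())
        if missing.size:
            shown = ", ".join(map(str, missing[:10]))
            more = f" (+{missing.size - 10} more)" if missing.size > 10 else ""
            raise ValueError(
                f"period {period!r}: no OD record for cells [{shown}]{more}"
            )
        arr = np.empty(grid.n_cells)
        arr[mins.index.to_numpy()] = mins.to_numpy()
        values[period] = arr + dispatch_minutes
    return ResponseField(grid, dispatch_minutes, values)
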