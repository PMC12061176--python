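import numpy as np
import pytest

from ems_access.access_surface import AccessSurface
from ems_access.grids import GridSpec, PopulationGrid, StationSet
from ems_access.partition import (
    ImpedanceRaster,
    compare_partition_models,
    impedance_from_surface,
    mcr_allocate,
    station_stats,
)

from oracles import nx_shortest_costs, octile_distance


def _grid(n=10, cell=100.0):
    return GridSpec(0.0, n * cell, cell, n, n)


def _stations_at_cells(grid, cells, ids=None):
    xy = grid.cell_centers_flat()[list(cells)]
    ids = ids if ids is not None else np.arange(1, len(cells) + 1)
    return StationSet(ids, xy[:, 0], xy[:, 1], np.ones(len(cells)))


class TestImpedance:
    def test_planar_surface_constant_gradient(self):
        """R = x/v (x in 100 m units) has slope 1/v min per 100 m, hence
        impedance 60/v s per 100 m everywhere."""
        v = 5.0
        grid = _grid(6, 100.0)
        xx, _ = grid.cell_centers()
        surf = AccessSurface(grid, "p", (xx / 100.0) / v)
        imp = impedance_from_surface(surf, floor_s_per_100m=0.1)
        np.testing.assert_allclose(imp.values, 60.0 / v, rtol=1e-9)

    def test_constant_surface_floors(self):
        grid = _grid(5)
        surf = AccessSurface(grid, "p", np.full((5, 5), 9.0))
        imp = impedance_from_surface(surf, floor_s_per_100m=1.0)
        np.testing.assert_array_equal(imp.values, 1.0)

    def test_all_masked_rejected(self):
        grid = _grid(3)
        surf = AccessSurface(grid, "p", np.ones((3, 3)), np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            impedance_from_surface(surf)


class TestMCRAllocation:
    def test_single_station_costs_are_shortest_paths(self, rng):
        grid = _grid(8, 100.0)
        vals = rng.uniform(1.0, 30.0, (8, 8))
        imp = ImpedanceRaster(grid, "p", vals, np.ones((8, 8), bool))
        part = mcr_allocate(imp, _stations_at_cells(grid, [12]))
        assert (part.assignment == 1).all()
        ref = nx_shortest_costs(vals / 100.0, 100.0, [12])
        np.testing.assert_allclose(part.cost.ravel(), ref[0], rtol=0, atol=1e-9)
        r, c = grid.cell_of_point(*grid.cell_centers_flat()[12])
        assert part.cost[r, c] == 0.0

    def test_high_cost_wall_diverts_to_far_station(self):
        """Cells behind a near-impassable wall must attach to the station
        on their own side, matching per-source shortest paths."""
        n = 15
        grid = _grid(n, 100.0)
        vals = np.ones((n, n))
        vals[:, 7] = 1e5  # wall between left and right halves
        imp = ImpedanceRaster(grid, "p", vals, np.ones((n, n), bool))
        st = _stations_at_cells(grid, [n * 7 + 2, n * 7 + 12])  # left, right
        part = mcr_allocate(imp, st)
        ref = nx_shortest_costs(vals / 100.0, 100.0, [n * 7 + 2, n * 7 + 12])
        best = np.argmin(ref, axis=0)
        np.testing.assert_allclose(
            part.cost.ravel(), ref[best, np.arange(n * n)], rtol=0, atol=1e-9
        )
        assert (part.assignment[:, :7] == 1).all()
        assert (part.assignment[:, 8:] == 2).all()

    def test_uniform_impedance_equals_grid_voronoi(self):
        """With homogeneous cost the allocation is the nearest-station
        partition in the 8-connected grid metric (octile distance), ties
        to the lower id."""
        n = 12
        grid = _grid(n, 100.0)
        imp = ImpedanceRaster(grid, "p", np.full((n, n), 4.0), np.ones((n, n), bool))
        cells = [5, n * n - 20, n * 6 + 2]
        st = _stations_at_cells(grid, cells, ids=np.array([3, 1, 2]))
        part = mcr_allocate(imp, st)
        centers = grid.cell_centers_flat()
        rows, cols = np.divmod(np.arange(n * n), n)
        srows, scols = np.divmod(np.array(cells), n)
        d = np.stack(
            [octile_distance(rows - sr, cols - sc) for sr, sc in zip(srows, scols)]
        )  # in station order 3,1,2
        ids = np.array([3, 1, 2])
        order = np.argsort(ids)
        d_sorted, ids_sorted = d[order], ids[order]
        near = np.argmin(d_sorted, axis=0)
        expected = ids_sorted[near]
        second = np.partition(d_sorted, 1, axis=0)
        clear = (second[1] - second[0]) > 1e-9  # off tie boundaries
        np.testing.assert_array_equal(
            part.assignment.ravel()[clear], expected[clear]
        )

    def test_tie_breaks_to_lower_station_id(self):
        grid = _grid(5, 100.0)
        imp = ImpedanceRaster(grid, "p", np.ones((5, 5)), np.ones((5, 5), bool))
        # stations symmetric about the center column
        st = _stations_at_cells(grid, [10, 14], ids=np.array([9, 4]))
        part = mcr_allocate(imp, st)
        assert part.assignment[2, 2] == 4  # equidistant center -> lower id


class TestStationStats:
    def _setup(self, pops, assignment_ids, surface_vals):
        n = len(pops)
        grid = GridSpec(0.0, 100.0, 100.0, 1, n)
        pop = PopulationGrid(grid, np.array([pops], dtype=float))
        surf = AccessSurface(grid, "p", np.array([surface_vals], dtype=float))
        from ems_access.partition import ServicePartition

        part = ServicePartition(
            grid, "p", np.unique(assignment_ids),
            np.array([assignment_ids]), np.zeros((1, n)), np.ones((1, n), bool),
        )
        return part, pop, surf

    def test_thirty_thousand_people_one_team(self):
        part, pop, surf = self._setup([30000.0], [1], [5.0])
        df = station_stats(part, pop, surf)
        assert df["demand_teams"].iloc[0] == pytest.approx(1.0)

    def test_large_station_demand(self):
        part, pop, surf = self._setup([441000.0], [1], [5.0])
        assert station_stats(part, pop, surf)["demand_teams"].iloc[0] == pytest.approx(14.7)

    def test_station_prts_aggregate_to_citywide(self, rng):
        """The population-weighted mean of station PRTs over a complete
        partition equals the citywide PRT on the same surface."""
        n = 12
        pops = rng.uniform(10, 1000, n)
        ids = rng.integers(1, 4, n)
        vals = rng.uniform(4, 16, n)
        part, pop, surf = self._setup(list(pops), list(ids), list(vals))
        df = station_stats(part, pop, surf)
        agg = (df["population"] * df["prt_minutes"]).sum() / df["population"].sum()
        city = (pops * vals).sum() / pops.sum()
        assert agg == pytest.approx(city, rel=1e-12)
        assert df["population"].sum() == pytest.approx(pops.sum())

    def test_zero_population_station_flagged(self):
        part, pop, surf = self._setup([100.0, 0.0], [1, 2], [5.0, 6.0])
        df = station_stats(part, pop, surf).set_index("station_id")
        assert df.loc[2, "zero_population"]
        assert df.loc[2, "demand_teams"] == 0.0
        assert np.isnan(df.loc[2, "prt_minutes"])


class TestModelComparison:
    def test_self_fit_is_perfect(self):
        """When the oracle is the heterogeneous accumulated cost itself,
        the regression is exact."""
        n = 10
        grid = _grid(n, 100.0)
        rng = np.random.default_rng(3)
        vals = rng.uniform(2.0, 20.0, (n, n))
        imp = ImpedanceRaster(grid, "p", vals, np.ones((n, n), bool))
        st = _stations_at_cells(grid, [0, 77])
        part = mcr_allocate(imp, st)
        rep = compare_partition_models(imp, st, part.cost.ravel() / 60.0)
        assert rep["heterogeneous"]["r2"] == pytest.approx(1.0, abs=1e-12)
        assert rep["heterogeneous"]["rmse_seconds"] == pytest.approx(0.0, abs=1e-9)

    def test_homogeneous_city_models_agree(self):
        from ems_access import CityConfig, generate_city, travel_time_matrix
        from ems_access import build_response_field, sample_travel_times
        from ems_access.access_surface import surface_from_field

        city = generate_city(
            CityConfig(seed=2, n_rows=25, n_cols=25, n_stations=5,
                       v_core=500.0, v_periphery=500.0, congestion={"00:00": 1.0})
        )
        tm = travel_time_matrix(city.stations.sorted_by_id(), city.speed_for("00:00"))
        od = sample_travel_times(city, k=5, time_matrices={"00:00": tm})
        rf = build_response_field(od, city.grid, 2.0)
        imp = impedance_from_surface(surface_from_field(rf, "00:00"))
        rep = compare_partition_models(imp, city.stations, tm.min(axis=0))
        assert abs(rep["heterogeneous"]["r2"] - rep["homogeneous"]["r2"]) < 0.01
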