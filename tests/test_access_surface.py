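import numpy as np
import pytest

from ems_access import (
    CityConfig,
    generate_city,
    sample_travel_times,
    build_response_field,
)
from ems_access.access_surface import (
    AccessSurface,
    InterpConfig,
    NumericalDegeneracyError,
    focal_clean,
    idw_points,
    interpolate_surface,
    krige_points,
    mask_populated,
    surface_from_field,
)
from ems_access.grids import GridSpec, PopulationGrid, resample_population
from ems_access.pipeline import _point_sample


def _sample_grid(n=8, cell=250.0):
    grid = GridSpec(0.0, n * cell, cell, n, n)
    return grid, grid.cell_centers_flat()


class TestKriging:
    def test_constant_samples_give_constant_surface(self):
        _, xy = _sample_grid()
        z = np.full(len(xy), 7.5)
        out = krige_points(xy, z, np.array([[10.0, 10.0], [900.0, 1500.0]]))
        np.testing.assert_allclose(out, 7.5, atol=1e-12)

    def test_planar_samples_with_linear_drift(self):
        """Samples on a plane a + bx + cy with the trend-aware config are
        reproduced to 1e-6 at the sample locations (and everywhere)."""
        _, xy = _sample_grid()
        z = 3.0 + 0.002 * xy[:, 0] - 0.001 * xy[:, 1]
        cfg = InterpConfig(drift="linear", clip_to_sample_range=False)
        out = krige_points(xy, z, xy, cfg)
        np.testing.assert_allclose(out, z, atol=1e-6)

    def test_exact_at_sample_points_with_zero_nugget(self, rng):
        _, xy = _sample_grid(10)
        z = np.sin(xy[:, 0] / 500.0) + 0.5 * np.cos(xy[:, 1] / 700.0) + 5.0
        out = krige_points(xy, z, xy, InterpConfig(nugget=0.0))
        np.testing.assert_allclose(out, z, atol=1e-6)

    def test_conflicting_coincident_samples_rejected(self):
        _, xy = _sample_grid(4)
        xy = np.vstack([xy, xy[0]])
        z = np.arange(len(xy), dtype=float)
        with pytest.raises(NumericalDegeneracyError):
            krige_points(xy, z, xy[:2])

    def test_beats_nearest_neighbor_against_oracle_truth(self):
        """On the synthetic city, kriging the 250 m response samples to
        100 m should track the oracle's true fine-resolution times more
        closely than nearest-neighbor resampling does."""
        city = generate_city(CityConfig(seed=11, n_rows=30, n_cols=30, n_stations=6,
                                        congestion={"00:00": 1.0}))
        od = sample_travel_times(city, k=len(city.stations))
        rf = build_response_field(od, city.grid, 2.0)
        fine = GridSpec(0.0, city.grid.origin_y, 100.0, 75, 75)
        surf = interpolate_surface(rf, fine, "00:00", InterpConfig())
        from ems_access.grids import SpeedField
        from ems_access import travel_time_matrix
        fine_speed = SpeedField(
            "00:00", fine, _point_sample(city.grid, city.speed_for("00:00").values, fine)
        )
        truth = travel_time_matrix(city.stations, fine_speed).min(axis=0) + 2.0
        nn = _point_sample(city.grid, rf.as_raster("00:00"), fine)
        rmse_krig = np.sqrt(np.mean((surf.values.ravel() - truth) ** 2))
        rmse_nn = np.sqrt(np.mean((nn.ravel() - truth) ** 2))
        assert rmse_krig < rmse_nn

    def test_idw_exact_at_samples(self):
        _, xy = _sample_grid(5)
        z = np.linspace(1.0, 9.0, len(xy))
        np.testing.assert_allclose(idw_points(xy, z, xy), z, atol=1e-12)


class TestFocalClean:
    def _surface(self, vals):
        vals = np.asarray(vals, dtype=float)
        grid = GridSpec(0.0, vals.shape[0] * 100.0, 100.0, *vals.shape)
        return AccessSurface(grid, "p", vals)

    def test_constant_surface_unchanged(self):
        s = self._surface(np.full((6, 6), 4.0))
        out = focal_clean(s, 3, 3.0)
        np.testing.assert_array_equal(out.values, s.values)

    def test_single_spike_replaced_neighbors_kept(self):
        """A 1000 spike in a field of 10s: the spike's neighbors are all
        10 (mean 10, sd 0), so the spike collapses to 10; each neighbor's
        own window contains the spike, giving a huge sd, so neighbors
        survive untouched."""
        vals = np.full((5, 5), 10.0)
        vals[2, 2] = 1000.0
        out = focal_clean(self._surface(vals), 3, 3.0)
        assert out.values[2, 2] == pytest.approx(10.0)
        expect = np.full((5, 5), 10.0)
        np.testing.assert_allclose(out.values, expect)

    def test_infinite_threshold_is_identity(self, rng):
        vals = rng.uniform(5, 15, size=(7, 7))
        s = self._surface(vals)
        out = focal_clean(s, 3, np.inf)
        np.testing.assert_array_equal(out.values, vals)

    def test_idempotent_on_clean_surface(self, rng):
        vals = rng.normal(10, 0.5, size=(9, 9))
        once = focal_clean(self._surface(vals), 3, 3.0)
        twice = focal_clean(once, 3, 3.0)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            focal_clean(self._surface(np.ones((4, 4))), 4, 3.0)


class TestPopulationMaskAndResampling:
    def test_uniform_population_keeps_all_cells(self):
        grid = GridSpec(0.0, 400.0, 100.0, 4, 4)
        s = AccessSurface(grid, "p", np.ones((4, 4)) * 5)
        pop = PopulationGrid(grid, np.ones((4, 4)))
        assert mask_populated(s, pop).mask.all()

    def test_single_populated_quadrant_masks_rest(self):
        grid = GridSpec(0.0, 400.0, 100.0, 4, 4)
        vals = np.zeros((4, 4))
        vals[:2, :2] = 3.0
        pop = PopulationGrid(grid, vals)
        s = AccessSurface(grid, "p", np.ones((4, 4)))
        m = mask_populated(s, pop).mask
        assert m[:2, :2].all() and not m[2:, :].any() and not m[:2, 2:].any()

    def test_mass_conserved_250m_to_100m(self, rng):
        src = GridSpec(0.0, 10 * 250.0, 250.0, 10, 10)
        pop = PopulationGrid(src, rng.uniform(0, 500, size=(10, 10)))
        dst = GridSpec(0.0, 2500.0, 100.0, 25, 25)
        out = resample_population(pop, dst)
        assert abs(out.total - pop.total) / pop.total < 1e-9

    def test_disjoint_extents_rejected(self):
        src = GridSpec(0.0, 1000.0, 100.0, 10, 10)
        pop = PopulationGrid(src, np.ones((10, 10)))
        far = GridSpec(99000.0, 1000.0, 100.0, 10, 10)
        with pytest.raises(ValueError, match="disjoint"):
            resample_population(pop, far)


def test_surface_from_field_roundtrip(small_city):
    od = sample_travel_times(small_city, k=3, periods=["00:00"])
    rf = build_response_field(od, small_city.grid, 2.0)
    s = surface_from_field(rf, "00:00")
    np.testing.assert_array_equal(s.values, rf.as_raster("00:00"))
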