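"""Tests for the synthetic fjord generator: geometry, autocorrelation,
effort bookkeeping, and biased presence sampling."""

import numpy as np
import pytest

from fjordsdm import synthetic
from fjordsdm.grids import GridError, RasterGrid
from fjordsdm.pseudo_absence import trackline_density
from fjordsdm.records import Trackline


class TestStaticLayers:
    def test_water_nonpositive_land_positive(self):
        depth, slope, dist = synthetic.gen_static_layers((16, 16), 500.0, seed=7)
        land = synthetic.land_mask_from_depth(depth)
        assert land.any() and (~land).any()
        assert np.all(depth.values[~land] <= 0)
        assert np.all(depth.values[land] > 0)

    def test_flat_depth_gives_zero_slope(self):
        flat = RasterGrid(np.full((12, 12), -50.0), 500.0)
        slope = synthetic.slope_from_depth(flat)
        assert np.allclose(slope.values, 0.0)

    def test_slope_matches_hand_finite_difference(self):
        depth, slope, _ = synthetic.gen_static_layers((16, 16), 500.0, seed=7)
        r, c = 8, 5  # interior water cell
        # np.gradient central difference, by hand from the neighbours
        dzdx = (depth.values[r, c + 1] - depth.values[r, c - 1]) / (2 * 500.0)
        dzdy = (depth.values[r + 1, c] - depth.values[r - 1, c]) / (2 * 500.0)
        expected = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        assert slope.values[r, c] == pytest.approx(expected, abs=1e-12)

    def test_cell_adjacent_to_land_is_one_cell_from_shore(self):
        depth, _, dist = synthetic.gen_static_layers((16, 16), 500.0, seed=7)
        land = synthetic.land_mask_from_depth(depth)
        # find a water cell 4-adjacent to land
        rows, cols = np.where(~land[:, :-1] & land[:, 1:])
        r, c = rows[0], cols[0]
        assert dist.values[r, c] == pytest.approx(500.0)
        assert np.all(dist.values[land] == 0)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(GridError):
            synthetic.gen_static_layers((4, 4), 500.0, seed=1)


class TestDynamicLayers:
    def test_same_seed_same_month_identical(self):
        a = synthetic.gen_dynamic_layer((20, 20), 500.0, "2019-06", "sst", seed=3)
        b = synthetic.gen_dynamic_layer((20, 20), 500.0, "2019-06", "sst", seed=3)
        assert np.array_equal(a.values, b.values)

    def test_different_month_differs(self):
        a = synthetic.gen_dynamic_layer((20, 20), 500.0, "2019-06", "sst", seed=3)
        b = synthetic.gen_dynamic_layer((20, 20), 500.0, "2019-07", "sst", seed=3)
        assert not np.array_equal(a.values, b.values)

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError, match="unknown dynamic layer"):
            synthetic.gen_dynamic_layer((20, 20), 500.0, "2019-06", "wind", seed=3)

    @pytest.mark.parametrize("name", ["sst", "chlorophyll_a", "salinity"])
    def test_values_within_physical_range(self, name):
        lo, hi = synthetic.DYNAMIC_RANGES[name]
        for month in ("2018-03", "2018-08"):
            layer = synthetic.gen_dynamic_layer((20, 20), 500.0, month, name, seed=5)
            assert layer.values.min() >= lo and layer.values.max() <= hi

    def test_smoothed_field_more_autocorrelated_than_permutation(self):
        layer = synthetic.gen_dynamic_layer((40, 40), 500.0, "2019-06", "sst", seed=3)

        def lag1_corr(v):
            return np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]

        rng = np.random.default_rng(0)
        perm = rng.permutation(layer.values.ravel()).reshape(layer.values.shape)
        assert lag1_corr(layer.values) > lag1_corr(perm) + 0.5

    def test_zero_radius_field_unsmoothed(self):
        raw = synthetic.gen_dynamic_layer((40, 40), 500.0, "2019-06", "salinity",
                                          seed=3, smooth_radius=0.0)

        def lag1_corr(v):
            return np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]

        assert abs(lag1_corr(raw.values)) < 0.15  # white noise, no spatial structure


class TestTrueSuitability:
    def test_zero_coefficients_give_half(self, small_world):
        stack = small_world["2018-05"].stack
        t = synthetic.make_true_suitability(stack, {}, 0.0)
        valid = ~t.surface.nodata_mask
        assert np.allclose(t.surface.values[valid], 0.5)

    def test_large_intercept_saturates(self, small_world):
        stack = small_world["2018-05"].stack
        t = synthetic.make_true_suitability(stack, {}, 20.0)
        assert np.all(t.surface.values[~t.surface.nodata_mask] > 0.999)

    def test_single_coefficient_preserves_rank_order(self, small_world):
        stack = small_world["2018-05"].stack
        t = synthetic.make_true_suitability(stack, {"depth": 0.3}, 0.0)
        valid = ~t.surface.nodata_mask
        depth = stack.layers["depth"].values[valid]
        order_d = np.argsort(depth, kind="stable")
        order_s = np.argsort(t.surface.values[valid], kind="stable")
        assert np.array_equal(order_d, order_s)

    def test_unknown_coefficient_rejected(self, small_world):
        stack = small_world["2018-05"].stack
        with pytest.raises(ValueError):
            synthetic.make_true_suitability(stack, {"wind": 1.0}, 0.0)


@pytest.fixture(scope="module")
def grid():
    depth, _, _ = synthetic.gen_static_layers((32, 32), 500.0, seed=42)
    return depth, synthetic.default_harbor(depth)


class TestTours:

    def test_zero_tours_zero_effort(self, grid):
        depth, harbor = grid
        tls, effort = synthetic.simulate_tours(depth, harbor, 0, "2018-05", seed=1)
        assert tls == [] and effort.effort_hours == 0 and effort.search_days == 0

    def test_effort_hours_is_three_per_tour(self, grid):
        depth, harbor = grid
        tls, effort = synthetic.simulate_tours(depth, harbor, 40, "2018-05", seed=1)
        assert effort.effort_hours == pytest.approx(120.0)
        assert len(tls) == 40

    def test_mean_tours_per_search_day_near_observed(self, grid):
        """The fleet runs ~1.43 tours per active day on average."""
        depth, harbor = grid
        ratios = []
        for seed in range(5):
            tls, effort = synthetic.simulate_tours(depth, harbor, 40, "2018-05", seed=seed)
            ratios.append(len(tls) / effort.search_days)
        assert np.mean(ratios) == pytest.approx(1.43, abs=0.3)

    def test_vertices_inside_extent(self, grid):
        depth, harbor = grid
        tls, _ = synthetic.simulate_tours(depth, harbor, 10, "2018-05", seed=3)
        xmin, ymin, xmax, ymax = depth.extent
        for tl in tls:
            assert np.all(tl.vertices[:, 0] >= xmin) and np.all(tl.vertices[:, 0] <= xmax)
            assert np.all(tl.vertices[:, 1] >= ymin) and np.all(tl.vertices[:, 1] <= ymax)

    def test_negative_tours_rejected(self, grid):
        depth, harbor = grid
        with pytest.raises(ValueError):
            synthetic.simulate_tours(depth, harbor, -1, "2018-05", seed=1)

    def test_determinism(self, grid):
        depth, harbor = grid
        a, ea = synthetic.simulate_tours(depth, harbor, 12, "2018-05", seed=9)
        b, eb = synthetic.simulate_tours(depth, harbor, 12, "2018-05", seed=9)
        assert ea == eb
        assert all(np.array_equal(x.vertices, y.vertices) for x, y in zip(a, b))


class TestSamplePresences:
    def test_zero_sightings_empty(self, small_world):
        md = small_world["2018-05"]
        truth = synthetic.make_true_suitability(md.stack, {"sst": 1.0}, 0.0)
        s = synthetic.sample_presences(truth, md.tracklines, 0, seed=1)
        assert len(s) == 0

    def test_uniform_suitability_follows_effort(self, small_world):
        """With flat habitat, sighting density tracks trackline density."""
        md = small_world["2018-05"]
        truth = synthetic.make_true_suitability(md.stack, {}, 0.0)
        s = synthetic.sample_presences(truth, md.tracklines, 400, seed=2)
        grid = truth.surface
        counts = np.zeros(grid.shape)
        for x, y in s.points:
            r, c = grid.point_to_cell(x, y)
            counts[r, c] += 1
        dens = trackline_density(md.tracklines, grid, bandwidth=2.0).grid.values
        from scipy.stats import spearmanr

        valid = ~grid.nodata_mask
        rho, _ = spearmanr(counts[valid], dens[valid])
        assert rho > 0.3

    def test_concentrated_suitability_concentrates_points(self, small_world):
        """Habitat confined to one quadrant attracts >80% of sightings."""
        md = small_world["2018-05"]
        grid = md.stack.grid
        nrows, ncols = grid.shape
        vals = np.full(grid.shape, 1e-6)
        vals[: nrows // 2, : ncols // 2] = 0.99  # north-west quadrant
        surface = synthetic.RasterGrid(vals, grid.cell_size, tuple(grid.origin),
                                       md.stack.combined_nodata())
        truth = synthetic.TrueSuitability({}, 0.0, surface)
        s = synthetic.sample_presences(truth, md.tracklines, 200, seed=3)
        in_quadrant = sum(
            1 for x, y in s.points
            if grid.point_to_cell(x, y)[0] < nrows // 2 and grid.point_to_cell(x, y)[1] < ncols // 2
        )
        assert in_quadrant / 200 > 0.8

    def test_points_on_water_and_inside_extent(self, small_world):
        md = small_world["2018-05"]
        truth = synthetic.make_true_suitability(md.stack, {"sst": 1.0}, 0.0)
        s = synthetic.sample_presences(truth, md.tracklines, 150, seed=4)
        nodata = md.stack.combined_nodata()
        for x, y in s.points:
            r, c = md.stack.grid.point_to_cell(x, y)
            assert not nodata[r, c]

    def test_no_water_under_tracklines_fails(self, small_world):
        md = small_world["2018-05"]
        grid = md.stack.grid
        all_masked = synthetic.RasterGrid(
            np.zeros(grid.shape), grid.cell_size, tuple(grid.origin),
            np.ones(grid.shape, dtype=bool),
        )
        truth = synthetic.TrueSuitability({}, 0.0, all_masked)
        with pytest.raises(Exception):
            synthetic.sample_presences(truth, md.tracklines, 10, seed=1)
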