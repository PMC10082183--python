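"""Adjacency construction, length-scale calibration and local smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotdecon import graph


def grid_xy(nx, ny):
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


class TestHistologyCoordinate:
    def test_equal_channels_pass_through(self):
        # identical RGB in a spot with equal channel variances -> z = c
        means = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0], [5.0, 5.0, 5.0]])
        hist = graph.combine_channels(means)
        assert np.allclose(hist.z, [1.0, 3.0, 5.0])

    def test_single_varying_channel_carries_all_weight(self):
        means = np.column_stack([
            np.array([0.0, 2.0, 4.0]),    # only red varies
            np.full(3, 7.0),
            np.full(3, 9.0),
        ])
        hist = graph.combine_channels(means)
        assert hist.channel_vars[1] == hist.channel_vars[2] == 0.0
        assert np.allclose(hist.z, means[:, 0])

    def test_variance_weighted_average(self):
        # three spots engineered so channel variances are exactly (1, 2, 3)
        # and the last spot has rgb (1, 2, 3): its z must be 14/6
        base = np.array([1.0, 2.0, 3.0])
        delta = np.sqrt(3.0 * np.array([1.0, 2.0, 3.0]) / 2.0)
        means = np.vstack([base + delta, base - delta, base])
        hist = graph.combine_channels(means)
        assert np.allclose(hist.channel_vars, [1.0, 2.0, 3.0])
        assert hist.z[-1] == pytest.approx(14.0 / 6.0, abs=1e-12)
        expect = (means @ np.array([1.0, 2.0, 3.0])) / 6.0
        assert np.allclose(hist.z, expect)

    def test_window_means_on_constant_blocks(self, rng):
        # image of two constant halves; windows entirely inside each half
        img = np.zeros((100, 200, 3))
        img[:, :100] = [10, 20, 30]
        img[:, 100:] = [50, 60, 70]
        pixel_xy = np.array([[40.0, 50.0], [160.0, 50.0]])  # (x=col, y=row)
        hist = graph.compute_histology_coordinate(img, pixel_xy, window=20)
        v = sum(hist.channel_vars)
        assert v > 0
        # each window mean is the half's constant color
        w = np.asarray(hist.channel_vars) / v
        assert hist.z[0] == pytest.approx(np.array([10, 20, 30.0]) @ w)
        assert hist.z[1] == pytest.approx(np.array([50, 60, 70.0]) @ w)

    def test_border_windows_are_clamped(self):
        img = np.tile(np.arange(60, dtype=float)[:, None, None], (1, 60, 3))
        pixel_xy = np.array([[0.0, 0.0], [59.0, 59.0]])
        hist = graph.compute_histology_coordinate(img, pixel_xy, window=50)
        assert np.all(np.isfinite(hist.z))

    def test_out_of_bounds_center_rejected(self):
        img = np.zeros((10, 10, 3))
        with pytest.raises(ValueError, match="outside the image"):
            graph.compute_histology_coordinate(img, np.array([[20.0, 5.0]]))

    def test_missing_inputs_signal_unavailable(self):
        with pytest.raises(graph.HistologyUnavailableError):
            graph.compute_histology_coordinate(None, np.zeros((2, 2)))
        with pytest.raises(graph.HistologyUnavailableError):
            graph.compute_histology_coordinate(np.zeros((5, 5, 3)), None)

    def test_degenerate_histology_errors(self):
        img = np.full((30, 30, 3), 128.0)
        px = np.array([[10.0, 10.0], [20.0, 20.0]])
        with pytest.raises(graph.DegenerateHistologyError):
            graph.compute_histology_coordinate(img, px, window=4)


class TestScaleHistology:
    def test_zero_scale_annihilates(self, rng):
        z = rng.normal(size=20)
        xy = rng.normal(size=(20, 2))
        assert np.all(graph.scale_histology(z, xy, 0.0) == 0)

    def test_constant_histology_gives_zeros(self, rng):
        xy = rng.normal(size=(15, 2))
        assert np.all(graph.scale_histology(np.full(15, 3.3), xy, 1.0) == 0)

    def test_variance_matches_wider_spatial_axis(self, rng):
        z = rng.normal(size=5000)
        xy = np.column_stack([rng.normal(0, 2.0, 5000), rng.normal(0, 1.0, 5000)])
        z_star = graph.scale_histology(z, xy, 1.0)
        # var(z*) = max(var(x), var(y)) exactly under the population convention
        assert np.var(z_star) == pytest.approx(max(np.var(xy[:, 0]), np.var(xy[:, 1])),
                                               rel=1e-12)

    def test_too_few_spots(self):
        with pytest.raises(ValueError, match="at least 2"):
            graph.scale_histology(np.array([1.0]), np.zeros((1, 2)), 1.0)


class TestDistanceAndAdjacency:
    def test_known_distances(self):
        xy = np.array([[0.0, 0.0], [3.0, 4.0]])
        D = graph.pairwise_distance(xy, np.zeros(2))
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 0] == 0.0
        D3 = graph.pairwise_distance(np.array([[1.0, 1.0], [2.0, 2.0]]),
                                     np.array([1.0, 2.0]))
        assert D3[0, 1] == pytest.approx(np.sqrt(3.0))

    def test_kernel_closed_form(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        adj = graph.adjacency_from_distance(D, l=2.0)
        assert adj.A[0, 1] == pytest.approx(np.exp(-0.5))
        assert np.all(np.diag(adj.A) == 1.0)

    def test_tiny_length_scale_kills_neighbors(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        adj = graph.adjacency_from_distance(D, l=1e-3)
        assert adj.A[0, 1] == pytest.approx(0.0, abs=1e-300)

    def test_invalid_length_scale(self):
        with pytest.raises(ValueError, match="positive"):
            graph.adjacency_from_distance(np.zeros((2, 2)), l=0.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(3, 25), st.integers(0, 1000))
    def test_symmetry_unit_diagonal_bounded(self, n, seed):
        r = np.random.default_rng(seed)
        D = graph.pairwise_distance(r.normal(size=(n, 2)))
        adj = graph.adjacency_from_distance(D, l=float(r.uniform(0.1, 3.0)))
        assert np.allclose(adj.A, adj.A.T)
        assert np.all(np.diag(adj.A) == 1.0)
        assert np.all((adj.A >= 0) & (adj.A <= 1.0))


class TestCalibration:
    def test_two_spot_closed_form(self):
        # a(1,2) = 0.5 requires l = d / sqrt(2 ln 2)
        d = 3.7
        D = np.array([[0.0, d], [d, 0.0]])
        l = graph.calibrate_length_scale(D, 0.5, tol=1e-9)
        assert l == pytest.approx(d / np.sqrt(2 * np.log(2)), rel=1e-4)

    @pytest.mark.parametrize("n", [10, 100, 400])
    def test_random_layouts_hit_target(self, n, rng):
        D = graph.pairwise_distance(rng.uniform(0, 30, size=(n, 2)))
        l = graph.calibrate_length_scale(D, 0.5, tol=1e-3)
        adj = graph.adjacency_from_distance(D, l)
        assert adj.mean_neighbor_weight == pytest.approx(0.5, abs=1e-3)

    def test_coordinate_scaling_scales_l(self, rng):
        xy = rng.uniform(0, 10, size=(50, 2))
        D = graph.pairwise_distance(xy)
        l1 = graph.calibrate_length_scale(D, 0.5, tol=1e-6)
        l2 = graph.calibrate_length_scale(
            graph.pairwise_distance(xy * 2.5), 0.5, tol=1e-6
        )
        assert l2 / l1 == pytest.approx(2.5, rel=1e-3)

    def test_unreachable_target_reports_achieved(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="target mean weight"):
            graph.calibrate_length_scale(D, 5.0)  # > n-1


class TestSmoothing:
    def test_identity_adjacency_is_noop(self, rng):
        X = rng.poisson(5, size=(6, 4)).astype(float)
        assert np.array_equal(graph.smooth_expression(np.eye(6), X), X)

    def test_two_spot_product(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        X = np.array([[2.0, 0.0], [0.0, 2.0]])
        assert np.allclose(graph.smooth_expression(A, X),
                           [[2.0, 1.0], [1.0, 2.0]])

    def test_small_l_limit_recovers_input(self, rng):
        xy = rng.uniform(0, 5, size=(30, 2))
        D = graph.pairwise_distance(xy)
        l = 1e-6 * D[D > 0].min()
        X = rng.poisson(10, size=(30, 8)).astype(float)
        X_star = graph.smooth_expression(graph.adjacency_from_distance(D, l), X)
        assert np.max(np.abs(X_star - X)) < 1e-6

    def test_preserves_nonnegativity(self, rng):
        D = graph.pairwise_distance(rng.uniform(0, 5, size=(20, 2)))
        adj = graph.adjacency_from_distance(D, 1.0)
        X = rng.poisson(3, size=(20, 10)).astype(float)
        assert np.all(graph.smooth_expression(adj, X) >= 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="align"):
            graph.smooth_expression(np.eye(3), np.zeros((4, 2)))


class TestBuildAdjacency:
    def test_zero_s_equals_pure_2d(self, rng):
        xy = grid_xy(6, 6)
        img = rng.uniform(0, 255, size=(130, 130, 3))
        px = (xy + 0.5) * 20
        with_s0 = graph.build_adjacency(xy, image=img, pixel_xy=px, s=0.0)
        pure = graph.build_adjacency(xy)
        assert np.allclose(with_s0.A, pure.A)

    def test_spots_without_coordinates_get_identity_rows(self, rng):
        xy = grid_xy(5, 5)
        xy[3] = np.nan  # unplaced spot: retained, not smoothed
        adj = graph.build_adjacency(xy)
        assert adj.A[3, 3] == 1.0
        assert np.all(np.delete(adj.A[3], 3) == 0.0)
        placed = np.delete(np.arange(25), 3)
        sub = adj.A[np.ix_(placed, placed)]
        n = len(placed)
        assert (sub.sum() - n) / n == pytest.approx(0.5, abs=1e-3)

    def test_histology_changes_weights(self, rng):
        xy = grid_xy(6, 6)
        img = rng.uniform(0, 255, size=(130, 130, 3))
        px = (xy + 0.5) * 20
        with_hist = graph.build_adjacency(xy, image=img, pixel_xy=px, s=1.0,
                                          window=10)
        pure = graph.build_adjacency(xy)
        assert not np.allclose(with_hist.A, pure.A)
        # both still calibrated to the same target
        assert with_hist.mean_neighbor_weight == pytest.approx(0.5, abs=1e-3)
        assert pure.mean_neighbor_weight == pytest.approx(0.5, abs=1e-3)
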