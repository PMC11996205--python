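"""Box counters: indices, oversampling, exact counting, regression FDs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fractaldim import (
    BoxGrid,
    ScalingCurve,
    box_index,
    boxcount_curve,
    count_boxes_exact,
    count_boxes_oversampled,
    count_boxes_points,
    fd_from_curve,
    local_fd_two_scale,
    oversample,
    rolling_fd,
    segment_crossings,
)
from .conftest import oracle_box_count


class TestBoxIndex:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.25, 0.07), (2, 0)),
            ((0.1, 0.0), (1, 0)),  # on a gridline -> upper box (half-open)
            ((-0.05, 0.0), (-1, 0)),  # floor toward -inf
        ],
    )
    def test_floor_convention(self, p, expected):
        assert box_index(p, BoxGrid(0.1)) == expected

    def test_origin_and_rotation(self):
        # shifting the origin by eps shifts the index by one
        assert box_index((0.25, 0.07), BoxGrid(0.1, origin=(0.1, 0.0))) == (1, 0)
        # quarter turn maps (x, y) to (y, -x) in the grid frame
        assert box_index((0.25, 0.07), BoxGrid(0.1, theta=np.pi / 2)) == (0, -3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            box_index((np.nan, 0.0), BoxGrid(0.1))


class TestPointCounting:
    def test_single_point_and_large_box(self):
        g = BoxGrid(10.0)
        assert count_boxes_points([(0.3, 0.4)], g) == 1
        pts = np.random.default_rng(0).uniform(0, 1, (50, 2))
        assert count_boxes_points(pts, BoxGrid(2.0)) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_boxes_points(np.empty((0, 2)), BoxGrid(1.0))

    def test_koch3_worked_example(self, koch3):
        """65 vertices on a 1/30 grid occupy 56 boxes; S=1 fills 8 more."""
        g = BoxGrid(1.0 / 30.0)
        assert count_boxes_points(koch3.points, g) == 56
        assert count_boxes_oversampled(koch3.points, 1, g) == 64


class TestOversample:
    def test_identity_at_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        assert np.array_equal(oversample(pts, 0), pts)

    def test_even_spacing(self):
        z = oversample(np.array([[0.0, 0.0], [1.0, 0.0]]), 3)
        assert np.allclose(z, [[0, 0], [0.25, 0], [0.5, 0], [0.75, 0], [1, 0]])

    @pytest.mark.parametrize("n,S", [(5, 2), (10, 7), (2, 0)])
    def test_size_and_vertex_subset(self, n, S):
        rng = np.random.default_rng(n * 10 + S)
        pts = rng.normal(size=(n, 2))
        z = oversample(pts, S)
        assert len(z) == (n - 1) * S + n
        assert np.allclose(z[:: S + 1], pts)

    @given(S=st.integers(0, 20), seed=st.integers(0, 100))
    def test_count_monotone_in_oversampling(self, S, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, (8, 2))
        g = BoxGrid(0.15)
        assert count_boxes_oversampled(pts, S, g) >= count_boxes_points(pts, g)


class TestSegmentCrossings:
    def test_diagonal_segment_crossings(self):
        z = segment_crossings((0.05, 0.05), (0.25, 0.15), BoxGrid(0.1))
        expected = [
            [0.05, 0.05],
            [0.1, 0.075],
            [0.15, 0.1],
            [0.2, 0.125],
            [0.25, 0.15],
        ]
        assert np.allclose(z, expected)

    def test_corner_crossing_deduplicated(self):
        z = segment_crossings((0.0, 0.0), (0.2, 0.2), BoxGrid(0.1))
        assert len(z) == 3
        assert np.allclose(z[1], [0.1, 0.1])

    def test_interior_segment_returns_endpoints(self):
        z = segment_crossings((0.01, 0.02), (0.07, 0.08), BoxGrid(0.1))
        assert np.allclose(z, [[0.01, 0.02], [0.07, 0.08]])


class TestExactCounting:
    def test_single_segment_boxes(self):
        g = BoxGrid(0.1)
        assert count_boxes_exact([(0.05, 0.05), (0.25, 0.15)], g) == 4
        assert count_boxes_exact([(0.0, 0.05), (0.35, 0.05)], g) == 4

    @pytest.mark.parametrize("k", [1, 2, 3, 7, 13, 29, 50])
    def test_unit_segment_closed_form(self, k):
        """A unit segment on an aligned 1/k grid spans boxes 0..k.

        The endpoint x=1 sits exactly on gridline k and belongs to box k
        under the half-open convention, giving k+1 boxes in total; the
        brute-force oracle agrees.
        """
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        g = BoxGrid(1.0 / k)
        assert count_boxes_exact(pts, g) == k + 1
        assert oracle_box_count(pts, g) == k + 1

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            count_boxes_exact(np.array([[0.0, 0.0]]), BoxGrid(0.1))
        # repeated frames contribute only their vertex box
        pts = np.array([[0.05, 0.05], [0.05, 0.05], [0.05, 0.05]])
        assert count_boxes_exact(pts, BoxGrid(0.1)) == 1

    def test_gridline_segment_assigned_upper_boxes(self):
        # a segment lying along y=0.1 belongs to the row above the line
        pts = np.array([[0.02, 0.1], [0.18, 0.1]])
        g = BoxGrid(0.1)
        assert count_boxes_exact(pts, g) == 2  # boxes (0,1),(1,1)

    def test_matches_brute_force_oracle_on_random_paths(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            pts = rng.uniform(0, 1, (21, 2))
            eps = rng.uniform(0.05, 0.3)
            g = BoxGrid(eps, origin=tuple(rng.uniform(0, eps, 2)))
            assert count_boxes_exact(pts, g) == oracle_box_count(pts, g)

    def test_oversampling_converges_to_exact(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            pts = rng.uniform(0, 1, (21, 2))
            g = BoxGrid(0.11, origin=(rng.uniform(0, 0.1), rng.uniform(0, 0.1)))
            counts = [count_boxes_oversampled(pts, S, g) for S in (0, 10, 100, 10_000)]
            exact = count_boxes_exact(pts, g)
            assert counts == sorted(counts)
            assert counts[-1] <= exact
            assert counts[-1] == exact  # no corner tangency in random floats


class TestGridInvariances:
    def test_translation_of_curve_and_grid(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, (15, 2))
        shift = np.array([1.7, -0.4])
        for counter in (count_boxes_points, count_boxes_exact):
            a = counter(pts, BoxGrid(0.13, origin=(0.02, 0.05)))
            b = counter(pts + shift, BoxGrid(0.13, origin=(0.02 + shift[0], 0.05 + shift[1])))
            assert a == b

    def test_grid_rotation_equals_counter_rotating_curve(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1, (15, 2))
        theta = 0.6
        c, s = np.cos(-theta), np.sin(-theta)
        rotated = pts @ np.array([[c, -s], [s, c]]).T
        for counter in (count_boxes_points, count_boxes_exact):
            assert counter(pts, BoxGrid(0.1, theta=theta)) == counter(
                rotated, BoxGrid(0.1)
            )

    def test_aligned_coarsening_monotonicity(self, koch3):
        # integer coarsening merges lam^2 boxes into one: N(lam*eps) <= N(eps)
        for lam in (2, 3):
            for eps in (0.02, 0.05):
                n_fine = count_boxes_exact(koch3.points, BoxGrid(eps))
                n_coarse = count_boxes_exact(koch3.points, BoxGrid(lam * eps))
                assert n_coarse <= n_fine


class TestScalingAndRegression:
    def test_counting_chain_across_scales(self, koch3):
        scales = np.logspace(-2.2, -0.8, 8)
        orig = boxcount_curve(koch3.points, scales, "original")
        over = boxcount_curve(koch3.points, scales, "oversample", S=5)
        exact = boxcount_curve(koch3.points, scales, "exact")
        assert np.all(orig.values <= over.values)
        assert np.all(over.values <= exact.values)

    def test_noise_free_power_law_recovered(self):
        scales = np.logspace(-3, -1, 10)
        curve = ScalingCurve(scales, scales**-1.5)
        est = fd_from_curve(curve)
        assert np.isclose(est.D, 1.5, atol=1e-12)
        assert np.isclose(est.r2, 1.0)

    def test_constant_counts_give_dimension_zero(self):
        curve = ScalingCurve(np.logspace(-2, -1, 5), np.full(5, 7.0))
        assert fd_from_curve(curve).D == 0.0

    def test_straight_line_dimension_one(self):
        pts = np.column_stack([np.linspace(0, 1, 500), np.zeros(500)])
        scales = np.array([1 / 32, 1 / 64, 1 / 128, 1 / 256])
        est = fd_from_curve(boxcount_curve(pts, scales, "exact"))
        assert abs(est.D - 1.0) < 0.05

    def test_subset_and_error_paths(self):
        curve = ScalingCurve(np.logspace(-2, -1, 6), np.logspace(1, 2, 6))
        est = fd_from_curve(curve, scale_subset=curve.scales[:3])
        assert est.scale_range[1] <= curve.scales[2] * (1 + 1e-12)
        with pytest.raises(ValueError):
            fd_from_curve(curve, scale_subset=curve.scales[:1])

    def test_out_of_range_dimension_flagged(self):
        curve = ScalingCurve(np.logspace(-2, -1, 5), np.logspace(-2, -1, 5) ** -2.5)
        est = fd_from_curve(curve)
        assert "dimension_out_of_range" in est.flags


class TestLocalAndRollingFD:
    @pytest.mark.parametrize(
        "n1,n2,expected",
        [(100, 40, np.log2(2.5)), (50, 50, 0.0), (80, 20, 2.0)],
    )
    def test_two_scale_formula(self, n1, n2, expected):
        assert np.isclose(local_fd_two_scale(n1, n2), expected)

    def test_two_scale_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            local_fd_two_scale(0, 10)

    def test_rolling_constant_on_power_law(self):
        scales = np.logspace(-3, -1, 30)
        curve = ScalingCurve(scales, 5.0 * scales**-1.26)
        centers, dims = rolling_fd(curve, window=5)
        assert len(dims) == 26
        assert np.allclose(dims, 1.26, atol=1e-9)

    def test_rolling_limits_original_vs_exact(self, koch3):
        """Point counting saturates (local D -> 0) where exact counting
        resolves the underlying piecewise-linear curve (local D -> 1)."""
        scales = 10.0 ** (-1.0 - 0.025 * np.arange(100))
        orig = boxcount_curve(koch3.points, scales, "original")
        exact = boxcount_curve(koch3.points, scales, "exact")
        _, d_orig = rolling_fd(orig, window=15)
        _, d_exact = rolling_fd(exact, window=15)
        assert d_orig[-1] < 0.05
        assert abs(d_exact[-1] - 1.0) < 0.05

    def test_window_validation(self):
        curve = ScalingCurve(np.logspace(-2, -1, 5), np.logspace(1, 2, 5))
        with pytest.raises(ValueError):
            rolling_fd(curve, window=6)
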