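"""Sway-metric battery: oracles, invariants, and the confidence ellipse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from posturekit.config import RunConfig
from posturekit.errors import ContractError
from posturekit.metrics import (
    aggregate_metrics,
    axis_path_length,
    compute_all,
    confidence_ellipse,
    confidence_ellipse_area,
    directional_max_range,
    mean_sway_velocity,
    sway_range,
    total_path_length,
)

from conftest import make_traj, random_walk

Q95 = sps.chi2.ppf(0.95, 2)  # ~5.991


def square_path(side=100.0, fs=100.0):
    corners = [(0, 0), (side, 0), (side, side), (0, side), (0, 0)]
    return make_traj(corners, fs=fs)


class TestPathLengths:
    def test_square_perimeter(self):
        assert total_path_length(square_path()) == pytest.approx(400.0)

    def test_constant_trajectory_zero_path(self):
        traj = make_traj(np.tile([5.0, -3.0], (100, 1)))
        assert total_path_length(traj) == 0.0

    def test_polygon_approximates_circle_circumference(self):
        theta = np.linspace(0, 2 * np.pi, 361)
        xy = 50.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        path = total_path_length(make_traj(xy))
        assert path == pytest.approx(2 * np.pi * 50.0, rel=1e-3)

    def test_square_axis_decomposition(self):
        traj = square_path()
        assert axis_path_length(traj, "ML") == pytest.approx(200.0)
        assert axis_path_length(traj, "AP") == pytest.approx(200.0)

    def test_pure_ap_ramp_isolates_axis(self):
        y = np.linspace(0, 100, 200)
        traj = make_traj(np.column_stack([np.zeros_like(y), y]))
        assert axis_path_length(traj, "ML") == 0.0
        assert axis_path_length(traj, "AP") == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_total_path_bounded_by_axis_paths(self, seed):
        traj = random_walk(np.random.default_rng(seed))
        ml, ap = axis_path_length(traj, "ML"), axis_path_length(traj, "AP")
        total = total_path_length(traj)
        assert max(ml, ap) <= total + 1e-9
        assert total <= ml + ap + 1e-9


class TestVelocity:
    def test_square_over_ten_seconds(self):
        # 5 samples, 4 intervals; fs chosen so duration is 10 s
        traj = square_path(fs=0.4)
        assert mean_sway_velocity(traj) == pytest.approx(40.0)

    def test_constant_trajectory_zero_velocity(self):
        traj = make_traj(np.tile([1.0, 1.0], (50, 1)))
        assert mean_sway_velocity(traj) == 0.0

    def test_velocity_duration_identity(self, rng):
        traj = random_walk(rng, n=300)
        v = mean_sway_velocity(traj)
        assert v * traj.duration == pytest.approx(total_path_length(traj), rel=1e-12)

    def test_refinement_stability_on_smooth_path(self):
        t1 = np.arange(0, 10, 0.01)
        t2 = np.arange(0, 10, 0.005)
        def path(t):
            return np.column_stack(
                [30 * np.sin(2 * np.pi * 0.4 * t), 20 * np.sin(2 * np.pi * 0.3 * t)]
            )
        v1 = mean_sway_velocity(make_traj(path(t1), fs=100.0))
        v2 = mean_sway_velocity(make_traj(path(t2), fs=200.0))
        assert abs(v2 - v1) / v1 < 0.01


class TestRanges:
    def test_ap_ramp_endpoints(self):
        y = np.linspace(-40, 60, 500)
        traj = make_traj(np.column_stack([np.zeros_like(y), y]))
        assert sway_range(traj, "AP") == pytest.approx(100.0)
        r, l, a, p = directional_max_range(traj)
        assert (a, p) == (pytest.approx(60.0), pytest.approx(40.0))

    def test_single_quadrant_floors_unvisited_directions(self):
        xy = np.abs(np.random.default_rng(0).normal(size=(100, 2))) + 1.0
        r, l, a, p = directional_max_range(make_traj(xy))
        assert l == 0.0 and p == 0.0 and r > 0 and a > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_directional_sum_equals_range_when_both_signs_occur(self, seed):
        traj = random_walk(np.random.default_rng(seed))
        r, l, a, p = directional_max_range(traj)
        if traj.y_ap.max() > 0 and traj.y_ap.min() < 0:
            assert a + p == pytest.approx(sway_range(traj, "AP"))
        if traj.x_ml.max() > 0 and traj.x_ml.min() < 0:
            assert r + l == pytest.approx(sway_range(traj, "ML"))

    def test_uncentered_trajectory_rejected(self):
        traj = make_traj([[0, 0], [1, 1]], centered=False)
        with pytest.raises(ContractError, match="center"):
            sway_range(traj, "AP")


class TestConfidenceEllipse:
    def test_circular_gaussian_matches_analytic_area(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(scale=1.0, size=(100_000, 2))
        area = confidence_ellipse_area(pts)
        assert area == pytest.approx(np.pi * Q95, rel=0.02)

    def test_identical_samples_degenerate(self):
        res = confidence_ellipse(np.tile([2.0, 3.0], (50, 1)))
        assert res.area == 0.0 and res.degenerate

    def test_collinear_samples_degenerate(self):
        t = np.linspace(0, 1, 100)
        res = confidence_ellipse(np.column_stack([t, 2 * t]))
        assert res.area == 0.0 and res.degenerate

    def test_scaling_law(self, rng):
        pts = rng.normal(size=(5000, 2))
        a1 = confidence_ellipse_area(pts)
        a3 = confidence_ellipse_area(3.0 * pts)
        assert a3 == pytest.approx(9.0 * a1, rel=1e-9)

    def test_f_variant_exceeds_chi2_at_small_n(self, rng):
        pts = rng.normal(size=(20, 2))
        assert confidence_ellipse_area(pts, method="f") > confidence_ellipse_area(pts)

    def test_general_covariances_match_sqrt_det(self, rng):
        for _ in range(5):
            a = rng.uniform(0.5, 3.0, size=(2, 2))
            cov = a @ a.T + 0.1 * np.eye(2)
            pts = rng.multivariate_normal([0, 0], cov, size=100_000)
            area = confidence_ellipse_area(pts)
            sample_cov = np.cov(pts, rowvar=False)
            expected = np.pi * Q95 * np.sqrt(np.linalg.det(sample_cov))
            assert area == pytest.approx(expected, rel=1e-9)


class TestComputeAll:
    def test_constant_trajectory_all_zero(self):
        m = compute_all(make_traj(np.tile([0.0, 0.0], (200, 1))))
        assert m.total_path == 0.0 and m.sway_area == 0.0 and m.area_degenerate
        assert m.duration == pytest.approx(199 / 100.0)

    def test_ml_directed_trial_orders_ranges(self):
        t = np.arange(0, 10, 0.01)
        xy = np.column_stack(
            [120 * np.sin(2 * np.pi * 0.2 * t), 5 * np.sin(2 * np.pi * 0.3 * t)]
        )
        m = compute_all(make_traj(xy))
        assert m.ml_sway_range > m.ap_sway_range

    @pytest.mark.parametrize("seed", range(10))
    def test_invariants_on_random_walks(self, seed):
        m = compute_all(random_walk(np.random.default_rng(seed)))
        assert all(
            getattr(m, f) >= 0
            for f in ("total_path", "ml_sway_range", "sway_area", "mean_velocity")
        )
        assert max(m.ml_total_path, m.ap_total_path) <= m.total_path + 1e-9
        assert m.total_path <= m.ml_total_path + m.ap_total_path + 1e-9
        assert m.ml_sway_range <= m.max_range_R + m.max_range_L + 1e-9
        assert m.ap_sway_range <= m.max_range_A + m.max_range_P + 1e-9
        assert m.mean_velocity * m.duration == pytest.approx(m.total_path)

    def test_axis_sum_velocity_config(self):
        cfg = RunConfig.from_dict({"velocity": {"mode": "axis_sum"}})
        traj = square_path()
        m = compute_all(traj, cfg)
        assert m.mean_velocity == pytest.approx(
            m.ml_mean_velocity + m.ap_mean_velocity
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        k=st.floats(0.1, 10.0),
        dx=st.floats(-50.0, 50.0),
        dy=st.floats(-50.0, 50.0),
    )
    def test_translation_invariance_and_scale_equivariance(self, seed, k, dx, dy):
        """Paths/ranges/velocities are translation invariant (after
        re-centering) and scale-equivariant; area scales as k^2."""
        base = random_walk(np.random.default_rng(seed), n=200)
        m = compute_all(base)

        shifted = make_traj(base.xy + [dx, dy] - (base.xy + [dx, dy]).mean(axis=0))
        ms = compute_all(shifted)
        assert ms.total_path == pytest.approx(m.total_path, rel=1e-9)
        assert ms.sway_area == pytest.approx(m.sway_area, rel=1e-9)
        assert ms.ml_sway_range == pytest.approx(m.ml_sway_range, rel=1e-9)

        scaled = make_traj(base.xy * k)
        mk = compute_all(scaled)
        assert mk.total_path == pytest.approx(k * m.total_path, rel=1e-9)
        assert mk.mean_velocity == pytest.approx(k * m.mean_velocity, rel=1e-9)
        assert mk.ap_sway_range == pytest.approx(k * m.ap_sway_range, rel=1e-9)
        assert mk.sway_area == pytest.approx(k**2 * m.sway_area, rel=1e-7)


class TestAggregation:
    def test_mean_of_two_trials(self, rng):
        a = compute_all(random_walk(rng))
        b = compute_all(random_walk(rng))
        agg = aggregate_metrics([a, b])
        assert agg.total_path == pytest.approx((a.total_path + b.total_path) / 2)

    def test_single_trial_identity(self, rng):
        a = compute_all(random_walk(rng))
        assert aggregate_metrics([a]) == a

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            aggregate_metrics([])
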