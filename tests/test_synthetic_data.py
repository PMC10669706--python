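"""Generators: OU stance sway, excursion trials, inverse force model,
metric-level cohorts."""

import numpy as np
import pytest

from posturekit.cop import COPTrajectory, OriginRef, compute_cop
from posturekit.errors import GeometryError, ParameterError
from posturekit.metrics import compute_all
from posturekit.simulate import (
    CohortSimParams,
    GroupSpec,
    MVEBatteryParams,
    MVESimParams,
    SwaySimParams,
    YOUNG_BASELINE,
    cop_to_forces,
    simulate_cohort,
    simulate_mve_battery_session,
    simulate_mve_battery_trial,
    simulate_mve_trial,
    simulate_quiet_stance,
)


class TestQuietStance:
    def test_zero_noise_gives_zero_trajectory(self):
        p = SwaySimParams(sigma=(0.0, 0.0), noise_sd=0.0, duration=5.0, seed=0)
        traj = simulate_quiet_stance(p)
        np.testing.assert_array_equal(traj.xy, 0.0)

    def test_seed_determinism(self):
        p = SwaySimParams(duration=5.0, seed=7)
        a, b = simulate_quiet_stance(p), simulate_quiet_stance(p)
        np.testing.assert_array_equal(a.xy, b.xy)
        assert a.provenance["seed"] == 7

    def test_stationary_variance_matches_closed_form(self):
        theta, sigma = 1.5, 4.0
        p = SwaySimParams(theta=(theta, theta), sigma=(sigma, sigma),
                          noise_sd=0.0, duration=1000.0, seed=11)
        traj = simulate_quiet_stance(p)
        target = sigma**2 / (2 * theta)
        # pool both (independent) axes: the OU autocorrelation time limits
        # the effective sample size of a single axis
        assert traj.xy.var(axis=0).mean() == pytest.approx(target, rel=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            SwaySimParams(theta=(0.0, 1.0))
        with pytest.raises(ParameterError):
            SwaySimParams(duration=-1.0)


class TestMVETrial:
    def test_noise_free_amplitude_exact(self):
        traj = simulate_mve_trial(
            MVESimParams(direction="A", amplitude=100.0, overshoot=0.0)
        )
        m = compute_all(traj)
        assert m.max_range_A == pytest.approx(100.0, abs=1e-9)
        assert m.max_range_P == 0.0

    def test_overshoot_raises_peak(self):
        traj = simulate_mve_trial(
            MVESimParams(direction="A", amplitude=100.0, overshoot=0.1)
        )
        assert compute_all(traj).max_range_A == pytest.approx(110.0, abs=1e-9)

    def test_mirror_symmetry_a_vs_p(self):
        a = simulate_mve_trial(MVESimParams(direction="A", amplitude=90.0, seed=3))
        p = simulate_mve_trial(MVESimParams(direction="P", amplitude=90.0, seed=3))
        ma, mp = compute_all(a), compute_all(p)
        assert ma.max_range_A == pytest.approx(mp.max_range_P)
        assert ma.total_path == pytest.approx(mp.total_path)

    def test_ml_trial_dominates_ml_axis(self):
        traj = simulate_mve_trial(
            MVESimParams(direction="L", amplitude=120.0,
                         sway=SwaySimParams(seed=5), seed=5)
        )
        m = compute_all(traj)
        assert m.ml_sway_range > m.ap_sway_range


class TestInverseForceModel:
    def plate_traj(self, xy, fs=100.0):
        return COPTrajectory(
            xy=np.asarray(xy, dtype=float), sampling_rate=fs,
            origin_reference=OriginRef((0.0, 0.0), "plate_origin"),
        )

    def test_center_splits_weight_equally(self, geometry):
        rec = cop_to_forces(self.plate_traj([[250, 250]] * 2), 600.0, geometry)
        np.testing.assert_allclose(rec.forces, 150.0)

    def test_near_corner_loads_that_cell(self, geometry):
        rec = cop_to_forces(self.plate_traj([[499.99, 0.01]] * 2), 600.0, geometry)
        assert rec.forces[0, 1] == pytest.approx(600.0, rel=1e-4)

    def test_sample_outside_rectangle_rejected_with_index(self, geometry):
        xy = [[250.0, 250.0], [250.0, 250.0], [600.0, 250.0]]
        with pytest.raises(GeometryError, match="sample 2"):
            cop_to_forces(self.plate_traj(xy), 600.0, geometry)

    def test_roundtrip_identity(self, geometry, rng):
        xy = rng.uniform(1.0, 499.0, size=(1000, 2))
        rec = cop_to_forces(self.plate_traj(xy), 700.0, geometry)
        back = compute_cop(rec)
        assert np.abs(back.xy - xy).max() < 1e-9
        np.testing.assert_allclose(rec.forces.sum(axis=1), 700.0)
        assert np.all(rec.forces >= 0)

    def test_centered_trajectory_restored_to_plate_frame(self, geometry):
        traj = COPTrajectory(
            xy=np.array([[0.0, 0.0], [10.0, -5.0]]), sampling_rate=100.0,
            origin_reference=OriginRef((250.0, 250.0), "initial_window"),
        )
        rec = cop_to_forces(traj, 600.0, geometry)
        back = compute_cop(rec)
        np.testing.assert_allclose(back.xy, [[250, 250], [260, 245]], atol=1e-9)


class TestBattery:
    def test_seed_determinism(self):
        a = simulate_mve_battery_trial(MVEBatteryParams(seed=9))
        b = simulate_mve_battery_trial(MVEBatteryParams(seed=9))
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_directional_maxima_near_stability_limits(self):
        p = MVEBatteryParams(amplitude_jitter=0.0, sway_amplitude=(0.0, 0.0), seed=0)
        m = compute_all(simulate_mve_battery_trial(p))
        assert m.max_range_R == pytest.approx(p.amp_R, rel=1e-6)
        assert m.max_range_L == pytest.approx(p.amp_L, rel=1e-6)
        assert m.max_range_A == pytest.approx(p.amp_A, rel=1e-6)
        assert m.max_range_P == pytest.approx(p.amp_P, rel=1e-6)

    def test_axis_paths_hit_targets_without_noise(self):
        p = MVEBatteryParams(amplitude_jitter=0.0, sway_amplitude=(0.0, 0.0), seed=0)
        m = compute_all(simulate_mve_battery_trial(p))
        assert m.ml_total_path == pytest.approx(p.ml_path, rel=0.01)
        assert m.ap_total_path == pytest.approx(p.ap_path, rel=0.01)

    def test_session_trials_differ_but_are_reproducible(self):
        s1 = simulate_mve_battery_session(n_trials=3, seed=2)
        s2 = simulate_mve_battery_session(n_trials=3, seed=2)
        assert len(s1) == 3
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.xy, b.xy)
        assert not np.array_equal(s1[0].xy, s1[1].xy)


class TestCohort:
    def test_seed_determinism(self):
        a = simulate_cohort(CohortSimParams(seed=5))
        b = simulate_cohort(CohortSimParams(seed=5))
        assert a.metrics.equals(b.metrics)
        assert a.outcomes.data.equals(b.outcomes.data)

    def test_default_design_shape(self):
        res = simulate_cohort(CohortSimParams(seed=1))
        sizes = (
            res.metrics.groupby("group").subject_id.nunique().to_dict()
        )
        assert sizes == {"experimental": 15, "control": 14}
        assert set(res.metrics.phase) == {"pre", "post"}
        assert res.metrics.parameter.nunique() == 13

    def test_large_sample_moments_converge(self):
        spec = {
            "big": GroupSpec(n=5000, baseline={"ml_sway_range": (166.0, 60.95)},
                             effect={"ml_sway_range": 75.58},
                             post_sd={"ml_sway_range": 50.42}),
            "other": GroupSpec(n=2, baseline={"ml_sway_range": (166.0, 60.95)}),
        }
        res = simulate_cohort(
            CohortSimParams(groups=spec, simulate_outcomes=False, seed=3)
        )
        big = res.metrics[res.metrics.group == "big"]
        pre = big[big.phase == "pre"].value
        post = big[big.phase == "post"].value
        assert pre.mean() == pytest.approx(166.0, rel=0.02)
        assert pre.std(ddof=1) == pytest.approx(60.95, rel=0.02)
        assert post.mean() == pytest.approx(166.0 + 75.58, rel=0.02)
        assert post.std(ddof=1) == pytest.approx(50.42, rel=0.02)
        # test-retest correlation
        wide = res.wide("pre").merge(
            res.wide("post"), on=["subject_id", "group"], suffixes=("_pre", "_post")
        )
        rho = np.corrcoef(
            wide.ml_sway_range_pre[wide.group == "big"],
            wide.ml_sway_range_post[wide.group == "big"],
        )[0, 1]
        assert rho == pytest.approx(0.7, abs=0.03)

    def test_outcomes_respect_scales(self):
        res = simulate_cohort(CohortSimParams(seed=8))
        data = res.outcomes.data
        assert data.bbs.between(0, 56).all()
        assert (data.tug_s > 0).all()
        assert (data.reach_cm >= 0).all()

    def test_young_battery_envelope_parameters_exposed(self):
        # the young normative table drives the battery defaults
        p = MVEBatteryParams()
        assert p.amp_R == YOUNG_BASELINE["max_range_R"][0]
        assert p.ml_path == YOUNG_BASELINE["ml_total_path"][0]
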