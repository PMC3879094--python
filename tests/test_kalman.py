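import math

import numpy as np
import pytest

from occlusim.geometry import ArcTrajectory, OccluderGeometry, bin_of_angle, emergence_angle
from occlusim.kalman import (
    CalibrationError,
    KalmanBelief,
    KalmanConfig,
    NumericalStateError,
    calibrate_predictive_noise,
    choose_bin_for_trial,
    extrapolate_choose_bin,
    kf_predict,
    kf_update,
    run_visible_phase,
    simulate_predictive_choices,
)


def make_belief(mean=None, var=1.0):
    m = np.zeros(6) if mean is None else np.asarray(mean, float)
    return KalmanBelief(mean=m, cov=var * np.eye(6))


class TestPredict:
    def test_stationary_fixed_point(self):
        cfg = KalmanConfig(process_noise_intensity=0.0)
        b = make_belief(mean=[3.0, -2.0, 0, 0, 0, 0])
        out = kf_predict(b, cfg)
        assert np.allclose(out.mean, b.mean)

    def test_tracks_quadratic_exactly(self):
        # constant-acceleration ground truth is inside the model class
        cfg = KalmanConfig(process_noise_intensity=0.0)
        p0, v, a = np.array([0.0, 0.0]), np.array([375.0, 10.0]), np.array([5.0, -40.0])
        b = make_belief(mean=np.concatenate([p0, v, a]), var=1e-12)
        t = 0.0
        for _ in range(30):
            b = kf_predict(b, cfg)
            t += cfg.dt
        expected = p0 + v * t + 0.5 * a * t * t
        assert np.allclose(b.mean[:2], expected, atol=1e-9)

    def test_hand_computed_covariance(self):
        # one step with identity covariance: P' = F F^T + Q, checked
        # against explicitly written matrix products
        cfg = KalmanConfig(process_noise_intensity=2.0)
        b = make_belief(var=1.0)
        out = kf_predict(b, cfg)
        f = cfg.transition_matrix()
        expected = f @ f.T + cfg.process_noise()
        assert np.allclose(out.cov, expected, atol=1e-12)

    def test_rejects_non_psd(self):
        cfg = KalmanConfig()
        bad = KalmanBelief(mean=np.zeros(6), cov=-np.eye(6))
        with pytest.raises(NumericalStateError):
            kf_predict(bad, cfg)


class TestUpdate:
    def test_scalar_closed_form(self):
        # prior var 1, obs var 1 -> posterior var 0.5, mean the average
        cfg = KalmanConfig(obs_noise_sd=1.0)
        b = make_belief(mean=[0, 0, 0, 0, 0, 0], var=1.0)
        out = kf_update(b, np.array([2.0, -4.0]), cfg)
        assert out.mean[0] == pytest.approx(1.0)
        assert out.mean[1] == pytest.approx(-2.0)
        assert out.cov[0, 0] == pytest.approx(0.5)
        assert out.cov[1, 1] == pytest.approx(0.5)

    def test_noiseless_observation_limit(self):
        cfg = KalmanConfig(obs_noise_sd=0.0)
        b = make_belief(var=10.0)
        out = kf_update(b, np.array([7.0, 3.0]), cfg)
        assert np.allclose(out.mean[:2], [7.0, 3.0], atol=1e-9)

    def test_uninformative_observation_limit(self):
        cfg = KalmanConfig(obs_noise_sd=1e9)
        b = make_belief(mean=[1.0, 2.0, 3, 4, 5, 6], var=1.0)
        out = kf_update(b, np.array([100.0, -100.0]), cfg)
        assert np.allclose(out.mean, b.mean, atol=1e-6)

    def test_posterior_variance_never_exceeds_prior(self, rng):
        cfg = KalmanConfig(obs_noise_sd=2.0, process_noise_intensity=1e3)
        b = make_belief(var=5.0)
        for _ in range(200):
            prior = kf_predict(b, cfg)
            post = kf_update(prior, rng.normal(size=2) * 10, cfg)
            assert post.cov[0, 0] <= prior.cov[0, 0] + 1e-12
            assert post.cov[1, 1] <= prior.cov[1, 1] + 1e-12
            post.check()
            b = post


class TestVisiblePhase:
    def test_frame_count(self):
        cfg = KalmanConfig()
        traj = ArcTrajectory(0.004, 0.0)
        # 125 px at 375 px/s and 75 Hz = 25 observed frames
        from occlusim.kalman import n_visible_frames

        assert n_visible_frames(traj, cfg) == 25

    def test_noiseless_terminal_position(self):
        cfg = KalmanConfig(obs_noise_sd=0.0, process_noise_intensity=1e6)
        traj = ArcTrajectory(0.0016, 0.0)
        rng = np.random.default_rng(0)
        b = run_visible_phase(traj, cfg, rng)
        # terminal position pinned to the last (noiseless) observation,
        # which is the occlusion point
        assert np.linalg.norm(b.mean[:2]) < 0.5

    def test_seeded_determinism(self):
        cfg = KalmanConfig(obs_noise_sd=2.0)
        traj = ArcTrajectory(0.004, 10.0)
        b1 = run_visible_phase(traj, cfg, np.random.default_rng(42))
        b2 = run_visible_phase(traj, cfg, np.random.default_rng(42))
        assert np.array_equal(b1.mean, b2.mean)


class TestBlindExtrapolation:
    def test_model_matched_straight_path(self, occ125):
        # straight shot at bin 11's center: velocity aimed at +4.5 deg
        cfg = KalmanConfig(process_noise_intensity=0.0)
        ang = math.radians(-4.5)  # clockwise-positive 4.5 -> math -4.5
        v = 375.0 * np.array([math.cos(ang), math.sin(ang)])
        b = make_belief(mean=np.concatenate([[0, 0], v, [0, 0]]), var=1e-9)
        pred = extrapolate_choose_bin(b, occ125, cfg)
        assert pred.bin == 11
        assert pred.angle == pytest.approx(4.5, abs=1e-6)
        assert not pred.fallback

    def test_gentle_curvature_small_bias(self, occ125):
        cfg = KalmanConfig(obs_noise_sd=0.0, process_noise_intensity=0.0)
        traj = ArcTrajectory(0.0016, 0.0)
        pred = choose_bin_for_trial(traj, occ125, cfg, np.random.default_rng(0))
        true_bin = bin_of_angle(emergence_angle(traj, occ125), occ125)
        assert abs(pred.bin - true_bin) <= 1

    def test_uncertainty_grows_every_blind_step(self, occ125):
        cfg = KalmanConfig(obs_noise_sd=1.0, process_noise_intensity=1e4)
        traj = ArcTrajectory(0.004, 0.0)
        b = run_visible_phase(traj, cfg, np.random.default_rng(1))
        traces = []
        cur = b
        for _ in range(20):
            cur = kf_predict(cur, cfg)
            traces.append(np.trace(cur.cov[:2, :2]))
        assert np.all(np.diff(traces) > 0)

    def test_covariance_psd_through_many_cycles(self, rng):
        cfg = KalmanConfig(obs_noise_sd=1.5, process_noise_intensity=1e3)
        b = make_belief(var=100.0)
        for _ in range(500):
            b = kf_predict(b, cfg)
            b = kf_update(b, rng.normal(size=2) * 50, cfg)
        b.check()


class TestBatchEquivalence:
    def test_matches_single_trial_noiseless(self, occ125):
        cfg = KalmanConfig(obs_noise_sd=0.0, process_noise_intensity=1e3)
        trajs = [ArcTrajectory(0.003, 15.0), ArcTrajectory(-0.007, -30.0),
                 ArcTrajectory(0.0016, 55.0)]
        bins, angles = simulate_predictive_choices(
            trajs, 125.0, cfg, np.random.default_rng(0)
        )
        for i, t in enumerate(trajs):
            single = choose_bin_for_trial(t, occ125, cfg, np.random.default_rng(0))
            assert single.bin == bins[i]
            assert single.angle == pytest.approx(angles[i], abs=1e-9)


class TestCalibration:
    def test_unreachable_target_raises(self, pretest_schedule):
        with pytest.raises(CalibrationError):
            calibrate_predictive_noise(
                0.99, pretest_schedule, sigma_grid=(6.0, 12.0), q_grid=(0.0,),
                n_seeds=1,
            )

    def test_target_outside_domain(self, pretest_schedule):
        with pytest.raises(ValueError):
            calibrate_predictive_noise(0.05, pretest_schedule)
        with pytest.raises(ValueError):
            calibrate_predictive_noise(1.0, pretest_schedule)
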