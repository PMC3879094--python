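import math

import numpy as np
import pytest
from scipy.stats import norm

from occlusim.geometry import ArcTrajectory
from occlusim.qpolicy import (
    PolicyConfig,
    QTable,
    calibrate_policy_noise,
    identify_state,
    perceive,
    q_update,
    run_policy_training,
    select_action,
    train_mapping_agent,
)
from occlusim.stimuli import ExperimentConfig, build_training_set


class TestPerception:
    def test_noiseless_identity(self, rng):
        cfg = PolicyConfig(sigma_theta=0.0, sigma_kappa=0.0)
        traj = ArcTrajectory(0.004, 17.0)
        assert perceive(traj, cfg, rng) == (17.0, 0.004)

    def test_unbiased(self):
        cfg = PolicyConfig(sigma_theta=5.0, sigma_kappa=0.001)
        traj = ArcTrajectory(0.004, 17.0)
        rng = np.random.default_rng(1)
        samples = np.array([perceive(traj, cfg, rng) for _ in range(20000)])
        se_theta = 5.0 / math.sqrt(len(samples))
        se_kappa = 0.001 / math.sqrt(len(samples))
        assert abs(samples[:, 0].mean() - 17.0) < 3 * se_theta
        assert abs(samples[:, 1].mean() - 0.004) < 3 * se_kappa


class TestStateIdentification:
    def make_table(self, protos):
        return QTable(values=np.zeros((len(protos), 20)), prototypes=np.array(protos))

    def test_exact_prototype(self):
        cfg = PolicyConfig(sigma_theta=1.0, sigma_kappa=0.001)
        table = self.make_table([[0.0, 0.002], [10.0, 0.004], [20.0, 0.006]])
        assert identify_state((10.0, 0.004), table, cfg) == 1

    def test_tie_goes_to_lowest_index(self):
        cfg = PolicyConfig(sigma_theta=1.0, sigma_kappa=1.0)
        table = self.make_table([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        # percept at 3.0 equidistant between prototypes 1 and 2
        assert identify_state((3.0, 0.0), table, cfg) == 1

    def test_misidentification_rate_matches_gaussian(self):
        # two prototypes 1 noise-SD apart along theta: P(misid) = Phi(-1/2)
        cfg = PolicyConfig(sigma_theta=4.0, sigma_kappa=0.0)
        table = self.make_table([[0.0, 0.004], [4.0, 0.004]])
        rng = np.random.default_rng(5)
        n = 40000
        wrong = 0
        traj = ArcTrajectory(0.004, 0.0)
        for _ in range(n):
            s = identify_state(perceive(traj, cfg, rng), table, cfg)
            wrong += s == 1
        p = norm.cdf(-0.5)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(wrong / n - p) < 4 * se


class TestActionSelection:
    def test_greedy_unique_max(self, rng):
        table = QTable(values=np.zeros((1, 20)), prototypes=np.zeros((1, 2)))
        table.values[0, 6] = 1.0
        assert all(select_action(table, 0, 0.0, rng) == 7 for _ in range(50))

    def test_full_exploration_uniform(self):
        table = QTable(values=np.zeros((1, 20)), prototypes=np.zeros((1, 2)))
        rng = np.random.default_rng(2)
        draws = np.array([select_action(table, 0, 1.0, rng) for _ in range(10000)])
        counts = np.bincount(draws, minlength=21)[1:]
        assert counts.min() > 0
        # each bin expected 500 +- ~66 (3 binomial SE)
        assert np.all(np.abs(counts - 500) < 3 * math.sqrt(10000 * 0.05 * 0.95) + 1)

    def test_all_equal_row_uniform_ties(self):
        table = QTable(values=np.zeros((1, 20)), prototypes=np.zeros((1, 2)))
        rng = np.random.default_rng(3)
        draws = {select_action(table, 0, 0.0, rng) for _ in range(2000)}
        assert draws == set(range(1, 21))


class TestValueUpdate:
    def test_single_step(self):
        table = QTable(values=np.zeros((1, 20)), prototypes=np.zeros((1, 2)))
        q_update(table, 0, 1, 1.0, 0.1)
        assert table.values[0, 0] == pytest.approx(0.1)

    def test_geometric_recursion(self):
        # n consecutive unit rewards from zero: Q_n = 1 - (1-alpha)^n
        table = QTable(values=np.zeros((1, 20)), prototypes=np.zeros((1, 2)))
        for _ in range(5):
            q_update(table, 0, 3, 1.0, 0.1)
        assert table.values[0, 2] == pytest.approx(1 - 0.9**5)
        assert table.values[0, 2] == pytest.approx(0.40951)

    def test_zero_fixed_point(self):
        table = QTable(values=np.zeros((1, 20)), prototypes=np.zeros((1, 2)))
        q_update(table, 0, 5, 0.0, 0.3)
        assert table.values[0, 4] == 0.0

    def test_values_bounded(self, rng):
        table = QTable(values=np.zeros((3, 20)), prototypes=np.zeros((3, 2)))
        for _ in range(5000):
            q_update(
                table,
                int(rng.integers(3)),
                int(rng.integers(20)) + 1,
                float(rng.integers(2)),
                0.3,
            )
        assert table.values.min() >= 0.0
        assert table.values.max() <= 1.0


class TestTraining:
    def test_noiseless_convergence_to_perfect(self, exp1):
        cfg = PolicyConfig(
            sigma_theta=0.0,
            sigma_kappa=0.0,
            epsilon_initial=0.2,
            epsilon_final=1e-6,
        )
        rng = np.random.default_rng(11)
        _, sched = build_training_set(exp1, "4Traj", rng)
        table, block_acc, _ = run_policy_training(sched, cfg, rng)
        assert block_acc[-1] > 0.95
        # greedy policy maps every prototype to its true bin
        from occlusim.geometry import OccluderGeometry, bin_of_angle, emergence_angle

        occ = OccluderGeometry(radius=125.0)
        for s in range(table.n_states):
            theta, kappa = table.prototypes[s]
            true_bin = bin_of_angle(
                emergence_angle(ArcTrajectory(kappa, theta), occ), occ
            )
            assert np.argmax(table.values[s]) + 1 == true_bin

    def test_learning_curve_improves(self, exp1):
        cfg = PolicyConfig(sigma_theta=2.0, sigma_kappa=0.0005)
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            _, sched = build_training_set(exp1, "4Traj", rng)
            _, block_acc, _ = run_policy_training(sched, cfg, rng)
            accs.append(block_acc)
        mean_acc = np.mean(accs, axis=0)
        assert mean_acc[-1] > mean_acc[0]

    def test_requires_feedback(self, exp1, rng):
        from occlusim.stimuli import sample_test_set

        sched = sample_test_set(exp1, 5, rng)
        with pytest.raises(ValueError):
            run_policy_training(sched, PolicyConfig(), rng)

    def test_set_size_degrades_terminal_accuracy(self):
        # the central confusability effect: more trajectories, less
        # discriminable states, worse terminal mapping accuracy
        cfg = PolicyConfig(sigma_theta=9.0, sigma_kappa=0.0024)
        exp = ExperimentConfig.exp1()
        from occlusim.sweep import simulate_sweep
        from occlusim.kalman import KalmanConfig

        res = simulate_sweep(
            exp,
            KalmanConfig(obs_noise_sd=1.0),
            cfg,
            seeds=tuple(range(6)),
            set_sizes=(4, 8, 12, 16, 20),
            n_trials=1200,
        )
        means = res.percent_correct_mapping.mean(axis=1)
        assert np.all(np.diff(means) < 0)


class TestPolicyCalibration:
    def test_hits_target(self, pretest_schedule):
        cfg, acc = calibrate_policy_noise(0.25, pretest_schedule, seed=3)
        assert abs(acc - 0.25) <= 0.03
        assert cfg.sigma_theta > 0 and cfg.sigma_kappa > 0

    def test_unreachable(self, pretest_schedule):
        from occlusim.kalman import CalibrationError

        with pytest.raises(CalibrationError):
            calibrate_policy_noise(
                0.999, pretest_schedule, scale_grid=np.array([20.0, 30.0])
            )
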