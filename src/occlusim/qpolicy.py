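"""Model-free (mapping) observer: tabular Q-learning over noisy percepts.

The agent never extrapolates.  On each trial it perceives the visible
trajectory's parameters (orientation, curvature) corrupted by Gaussian
sensory noise, identifies the nearest stored training trajectory
("state") under a noise-scaled distance, and responds with the bin
that currently has the highest learned action value for that state.
Feedback trials reward the chosen bin when it matches the true
emergence bin and the value table is updated incrementally.

Because the state set contains only the training trajectories, any
novel stimulus is forced onto the nearest trained exemplar -- the
nearest-bin overgeneralization that characterizes the mapping strategy
at transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ArcTrajectory, OccluderGeometry, emergence_angles, bin_of_angle

__all__ = [
    "QTable",
    "PolicyConfig",
    "perceive",
    "identify_state",
    "select_action",
    "q_update",
    "run_policy_training",
    "calibrate_policy_noise",
    "ideal_extrapolator_accuracy",
]


@dataclass(frozen=True)
class PolicyConfig:
    """Learning and perception hyperparameters of the mapping agent.

    ``epsilon`` decays exponentially from ``epsilon_initial`` to
    ``epsilon_final`` over the trials of a session, leaving residual
    exploration at the end of training.  ``sigma_theta`` (degrees) and
    ``sigma_kappa`` (1/px) are the sensory noise SDs on the perceived
    orientation and curvature.
    """

    learning_rate: float = 0.3
    epsilon_initial: float = 0.2
    epsilon_final: float = 0.01
    sigma_theta: float = 9.0
    sigma_kappa: float = 0.0025
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        for eps in (self.epsilon_initial, self.epsilon_final):
            if not 0.0 <= eps <= 1.0:
                raise ValueError("epsilon must lie in [0, 1]")
        if self.sigma_theta < 0 or self.sigma_kappa < 0:
            raise ValueError("sensory noise SDs must be non-negative")

    def epsilon_at(self, trial: int, n_trials: int) -> float:
        """Exploration rate on 0-based ``trial`` of an ``n_trials`` session."""
        if n_trials <= 1 or self.epsilon_initial == 0:
            return self.epsilon_final
        frac = trial / (n_trials - 1)
        lo = max(self.epsilon_final, 1e-12)
        return float(self.epsilon_initial * (lo / self.epsilon_initial) ** frac)


@dataclass
class QTable:
    """Action-value lookup: one row per training trajectory, 20 columns."""

    values: np.ndarray
    prototypes: np.ndarray  # (n_states, 2): columns (orientation_deg, curvature)

    @classmethod
    def for_prototypes(cls, trajectories: list[ArcTrajectory], n_bins: int = 20) -> "QTable":
        protos = np.array([[t.orientation, t.curvature] for t in trajectories])
        return cls(values=np.zeros((len(trajectories), n_bins)), prototypes=protos)

    @property
    def n_states(self) -> int:
        return self.values.shape[0]


def perceive(
    traj: ArcTrajectory, config: PolicyConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Noisy, unbiased percept of (orientation, curvature)."""
    theta_hat = traj.orientation + config.sigma_theta * rng.standard_normal()
    kappa_hat = traj.curvature + config.sigma_kappa * rng.standard_normal()
    return float(theta_hat), float(kappa_hat)


def identify_state(
    percept: tuple[float, float], table: QTable, config: PolicyConfig
) -> int:
    """Index of the nearest stored trajectory under noise-scaled distance.

    Each axis is divided by its sensory-noise SD (unit scale when the
    SD is zero); ties resolve to the lowest index.
    """
    if table.n_states == 0:
        raise ValueError("empty prototype set")
    st = config.sigma_theta if config.sigma_theta > 0 else 1.0
    sk = config.sigma_kappa if config.sigma_kappa > 0 else 1.0
    d2 = ((table.prototypes[:, 0] - percept[0]) / st) ** 2 + (
        (table.prototypes[:, 1] - percept[1]) / sk
    ) ** 2
    return int(np.argmin(d2))


def select_action(
    table: QTable, state: int, epsilon: float, rng: np.random.Generator
) -> int:
    """Epsilon-greedy bin choice (1-based); greedy ties break uniformly."""
    n_bins = table.values.shape[1]
    if rng.random() < epsilon:
        return int(rng.integers(n_bins)) + 1
    row = table.values[state]
    maxima = np.flatnonzero(row == row.max())
    return int(rng.choice(maxima)) + 1

def q_update(
    table: QTable, state: int, action: int, reward: float, learning_rate: float
) -> QTable:
    """Single-step value update Q(s,a) += alpha * (r - Q(s,a)).

    The task is one decision per trial, so there is no bootstrapping
    term.  Mutates and returns the table.
    """
    a = action - 1
    table.values[state, a] += learning_rate * (reward - table.values[state, a])
    return table


def run_policy_training(
    schedule,
    config: PolicyConfig,
    rng: np.random.Generator,
    table: QTable | None = None,
) -> tuple[QTable, np.ndarray, np.ndarray]:
    """Full perceive -> identify -> act -> feedback -> update loop.

    ``schedule`` must contain feedback trials.  Returns the learned
    table, per-block accuracy averages, and the per-trial chosen bins.
    """
    trials = [t for t in schedule.trials if t.feedback]
    if not trials:
        raise ValueError("schedule contains no feedback trials")
    if table is None:
        seen: list[ArcTrajectory] = []
        for t in trials:
            if t.trajectory not in seen:
                seen.append(t.trajectory)
        table = QTable.for_prototypes(seen, n_bins=config.n_bins)
    n = len(trials)
    choices = np.zeros(n, dtype=int)
    correct = np.zeros(n, dtype=bool)
    blocks = np.array([t.block for t in trials])
    for i, t in enumerate(trials):
        percept = perceive(t.trajectory, config, rng)
        state = identify_state(percept, table, config)
        action = select_action(table, state, config.epsilon_at(i, n), rng)
        reward = 1.0 if action == t.true_bin else 0.0
        q_update(table, state, action, reward, config.learning_rate)
        choices[i] = action
        correct[i] = reward > 0
    block_acc = np.array([correct[blocks == b].mean() for b in np.unique(blocks)])
    return table, block_acc, choices


def train_mapping_agent(
    prototypes: np.ndarray,
    true_bins: np.ndarray,
    order: np.ndarray,
    config: PolicyConfig,
    rng: np.random.Generator,
) -> tuple[QTable, np.ndarray]:
    """Array-based training loop used by the set-size sweep.

    ``prototypes`` is (m, 2) of (orientation, curvature); ``true_bins``
    (m,) their emergence bins; ``order`` the per-trial prototype index
    sequence.  Returns the table and per-trial chosen bins.
    """
    m = len(prototypes)
    table = QTable(values=np.zeros((m, config.n_bins)), prototypes=np.asarray(prototypes, float))
    st = config.sigma_theta if config.sigma_theta > 0 else 1.0
    sk = config.sigma_kappa if config.sigma_kappa > 0 else 1.0
    scaled = table.prototypes / np.array([st, sk])
    n = len(order)
    noise = rng.standard_normal((n, 2)) * np.array(
        [config.sigma_theta / st, config.sigma_kappa / sk]
    )
    explore = rng.random(n)
    eps = np.array([config.epsilon_at(i, n) for i in range(n)])
    choices = np.zeros(n, dtype=int)
    alpha = config.learning_rate
    values = table.values
    for i, proto_idx in enumerate(order):
        percept = scaled[proto_idx] + noise[i]
        d2 = np.sum((scaled - percept) ** 2, axis=1)
        state = int(np.argmin(d2))
        if explore[i] < eps[i]:
            action = int(rng.integers(config.n_bins))
        else:
            row = values[state]
            maxima = np.flatnonzero(row == row.max())
            action = int(rng.choice(maxima))
        reward = 1.0 if action + 1 == true_bins[proto_idx] else 0.0
        values[state, action] += alpha * (reward - values[state, action])
        choices[i] = action + 1
    return table, choices


def ideal_extrapolator_accuracy(
    curvatures: np.ndarray,
    orientations: np.ndarray,
    true_bins: np.ndarray,
    radius: float,
    sigma_theta: float,
    sigma_kappa: float,
    rng: np.random.Generator,
    n_reps: int = 20,
    occ: OccluderGeometry | None = None,
) -> float:
    """Accuracy of a perfect extrapolator fed noisy (theta, kappa) percepts.

    The benchmark used to equate the mapping agent's input quality with
    the calibrated predictive observer: the percept is converted to an
    emergence angle by exact geometry (clamped to the curved edge) and
    binned.  Monte Carlo over ``n_reps`` percepts per trial.
    """
    if occ is None:
        occ = OccluderGeometry(radius=radius)
    kappa = np.asarray(curvatures, float)
    theta = np.asarray(orientations, float)
    n = len(kappa)
    k_hat = kappa[None, :] + sigma_kappa * rng.standard_normal((n_reps, n))
    t_hat = theta[None, :] + sigma_theta * rng.standard_normal((n_reps, n))
    arg = np.clip(np.abs(k_hat) * radius / 2.0, 0.0, 1.0)
    d = np.degrees(np.arcsin(arg))
    phi = t_hat - np.sign(k_hat) * d
    phi = np.clip(phi, -90.0, 90.0)
    bins = np.minimum(
        np.floor((phi + 90.0) / occ.bin_span).astype(int) + 1, occ.bin_count
    )
    return float(np.mean(bins == np.asarray(true_bins, int)[None, :]))


def calibrate_policy_noise(
    target_accuracy: float,
    schedule,
    base_config: PolicyConfig | None = None,
    scale_grid: np.ndarray | None = None,
    n_reps: int = 20,
    seed: int = 0,
    tolerance: float = 0.03,
) -> tuple[PolicyConfig, float]:
    """Set (sigma_theta, sigma_kappa) so an ideal extrapolator fed the
    noisy percepts matches the calibrated predictive observer's
    pre-test accuracy.

    This makes the two strategies differ in *strategy*, not in input
    quality.  The two SDs are yoked to a single scale ``s`` split so
    that orientation noise and curvature noise contribute equally to
    emergence-angle noise: ``sigma_theta = s / sqrt(2)`` and
    ``sigma_kappa = s / (sqrt(2) * g)`` with ``g`` the mean
    |d phi / d kappa| over the calibration trials.
    """
    from .kalman import CalibrationError

    base = base_config or PolicyConfig()
    trials = list(schedule.trials)
    radius = trials[0].radius
    kappa = np.array([t.trajectory.curvature for t in trials])
    theta = np.array([t.trajectory.orientation for t in trials])
    true_bins = np.array([t.true_bin for t in trials])
    half = np.abs(kappa) * radius / 2.0
    g = float(np.mean(np.degrees(radius / 2.0 / np.sqrt(1.0 - half**2))))
    if scale_grid is None:
        scale_grid = np.arange(1.0, 40.5, 0.5)
    rng = np.random.default_rng(seed)
    best = None
    achieved = []
    for s in scale_grid:
        st = s / np.sqrt(2.0)
        sk = s / (np.sqrt(2.0) * g)
        acc = ideal_extrapolator_accuracy(
            kappa, theta, true_bins, radius, st, sk, rng, n_reps=n_reps
        )
        achieved.append(acc)
        gap = abs(acc - target_accuracy)
        if best is None or gap < best[0]:
            best = (gap, replace(base, sigma_theta=float(st), sigma_kappa=float(sk)), acc)
    assert best is not None
    if best[0] > tolerance:
        raise CalibrationError(
            f"target {target_accuracy} unreachable; achieved range "
            f"[{min(achieved):.3f}, {max(achieved):.3f}]"
        )
    return best[1], best[2]
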