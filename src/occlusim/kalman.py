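"""Model-based (predictive) observer: a constant-acceleration Kalman filter.

The observer tracks the visible dot with a 2-D nearly-constant-
acceleration linear state-space model (state: position, velocity,
acceleration per axis; process noise: white jerk of intensity ``q``).
While the dot is visible it cycles predict -> observe -> correct on
position observations corrupted by isotropic Gaussian noise.  Once the
dot is occluded it runs prediction steps only ("blind" extrapolation)
until the predicted mean crosses the occluder's curved edge, and
responds with the bin containing the crossing angle.

Circular motion is deliberately outside the model class: the filter's
systematic extrapolation bias on curved paths (an effective
underestimate of accumulated curvature) is part of the phenomenon
being modelled, not a defect.

Because the model is linear-Gaussian, covariance and gain sequences do
not depend on the observations; :func:`simulate_predictive_choices`
exploits this to run whole sessions as batched matrix algebra and is
exactly equivalent to the per-trial loop (up to shared random draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ArcTrajectory, OccluderGeometry, arc_state, bin_of_angle

__all__ = [
    "KalmanBelief",
    "KalmanConfig",
    "BlindPrediction",
    "NumericalStateError",
    "CalibrationError",
    "kf_predict",
    "kf_update",
    "run_visible_phase",
    "extrapolate_choose_bin",
    "simulate_predictive_choices",
    "calibrate_predictive_noise",
]


class NumericalStateError(RuntimeError):
    """A belief's covariance has lost symmetry or positive semidefiniteness."""


class CalibrationError(RuntimeError):
    """The noise grid cannot reach the requested target accuracy."""


@dataclass(frozen=True)
class KalmanConfig:
    """Filter constants.

    ``dt`` is the frame interval of the reference display (75 Hz);
    ``obs_noise_sd`` is the standard deviation of the isotropic
    position observation noise in px; ``process_noise_intensity`` is
    the white-jerk intensity ``q`` (px^2/s^5).  The initial covariance
    is diagonal and deliberately large -- 25 visible frames of burn-in
    make the initialization weakly influential.
    """

    dt: float = 1.0 / 75.0
    obs_noise_sd: float = 3.0
    process_noise_intensity: float = 0.0
    init_pos_var: float = 1e4
    init_vel_var: float = 1e4
    init_acc_var: float = 1e4
    max_blind_frames: int = 300

    def transition_matrix(self) -> np.ndarray:
        dt = self.dt
        f3 = np.array([[1.0, dt, dt * dt / 2.0], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
        return np.kron(f3, np.eye(2))

    def process_noise(self) -> np.ndarray:
        dt = self.dt
        q3 = np.array(
            [
                [dt**5 / 20.0, dt**4 / 8.0, dt**3 / 6.0],
                [dt**4 / 8.0, dt**3 / 3.0, dt**2 / 2.0],
                [dt**3 / 6.0, dt**2 / 2.0, dt],
            ]
        )
        return self.process_noise_intensity * np.kron(q3, np.eye(2))

    def observation_matrix(self) -> np.ndarray:
        h = np.zeros((2, 6))
        h[0, 0] = h[1, 1] = 1.0
        return h

    def initial_covariance(self) -> np.ndarray:
        return np.diag(
            [
                self.init_pos_var,
                self.init_pos_var,
                self.init_vel_var,
                self.init_vel_var,
                self.init_acc_var,
                self.init_acc_var,
            ]
        )


@dataclass
class KalmanBelief:
    """Gaussian belief over (px, py, vx, vy, ax, ay)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(6)
        self.cov = np.asarray(self.cov, dtype=float).reshape(6, 6)

    def check(self, tol: float = 1e-6) -> None:
        if not np.allclose(self.cov, self.cov.T, atol=tol):
            raise NumericalStateError("covariance not symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -tol:
            raise NumericalStateError("covariance not positive semidefinite")


@dataclass(frozen=True)
class BlindPrediction:
    """Outcome of the occluded extrapolation."""

    bin: int
    angle: float
    n_steps: int
    fallback: bool = False


def kf_predict(belief: KalmanBelief, config: KalmanConfig) -> KalmanBelief:
    """Time update: propagate the belief one frame with no observation."""
    belief.check()
    f = config.transition_matrix()
    mean = f @ belief.mean
    cov = f @ belief.cov @ f.T + config.process_noise()
    cov = 0.5 * (cov + cov.T)
    return KalmanBelief(mean=mean, cov=cov)


def kf_update(
    belief: KalmanBelief, observation: np.ndarray, config: KalmanConfig
) -> KalmanBelief:
    """Measurement update with an observed 2-D position.

    Joseph-form covariance update for numerical robustness; the
    posterior position variance never exceeds the prior's.
    """
    belief.check()
    obs = np.asarray(observation, dtype=float).reshape(2)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observation must be finite")
    h = config.observation_matrix()
    r = config.obs_noise_sd**2 * np.eye(2)
    s = h @ belief.cov @ h.T + r
    if np.linalg.matrix_rank(s) < 2:
        raise NumericalStateError("singular innovation covariance")
    k = belief.cov @ h.T @ np.linalg.inv(s)
    mean = belief.mean + k @ (obs - h @ belief.mean)
    ikh = np.eye(6) - k @ h
    cov = ikh @ belief.cov @ ikh.T + k @ r @ k.T
    cov = 0.5 * (cov + cov.T)
    return KalmanBelief(mean=mean, cov=cov)


def n_visible_frames(traj: ArcTrajectory, config: KalmanConfig) -> int:
    """Frames at which the dot is observed (last one at the occlusion point)."""
    return int(round(traj.visible_length / (traj.speed * config.dt)))


def _visible_arclengths(traj: ArcTrajectory, config: KalmanConfig) -> np.ndarray:
    n = n_visible_frames(traj, config)
    step = traj.speed * config.dt
    return -traj.visible_length + step * np.arange(1, n + 1)


def run_visible_phase(
    traj: ArcTrajectory, config: KalmanConfig, rng: np.random.Generator
) -> KalmanBelief:
    """Track the visible portion of the arc, returning the terminal belief.

    Observations are true arc positions plus isotropic Gaussian noise.
    The belief is initialized at the first observation with zero
    velocity and acceleration and a large diagonal covariance, then
    refined by predict/update cycles over the remaining frames.
    """
    svals = _visible_arclengths(traj, config)
    noise = config.obs_noise_sd * rng.standard_normal((len(svals), 2))
    obs = np.array([arc_state(traj, s)[0] for s in svals]) + noise
    mean = np.zeros(6)
    mean[:2] = obs[0]
    belief = KalmanBelief(mean=mean, cov=config.initial_covariance())
    for z in obs[1:]:
        belief = kf_predict(belief, config)
        belief = kf_update(belief, z, config)
    return belief


def _crossing_angle(
    inside: np.ndarray, outside: np.ndarray, radius: float
) -> tuple[float, bool]:
    """Angle (clockwise degrees) where the segment inside->outside crosses
    the circle |p| = radius; fallback flag set when the crossing lies in
    the -x half-plane (straight-edge exit) and is projected to +/-90."""
    d = outside - inside
    a = d @ d
    b = 2.0 * inside @ d
    c = inside @ inside - radius**2
    disc = max(b * b - 4 * a * c, 0.0)
    t = (-b + math.sqrt(disc)) / (2 * a) if a > 0 else 0.0
    t = min(max(t, 0.0), 1.0)
    p = inside + t * d
    phi = -math.degrees(math.atan2(p[1], p[0]))
    if abs(phi) > 90.0:
        return math.copysign(90.0, phi), True
    return phi, False


def extrapolate_choose_bin(
    belief: KalmanBelief, occ: OccluderGeometry, config: KalmanConfig
) -> BlindPrediction:
    """Blind extrapolation through occlusion and bin choice.

    Runs prediction-only steps until the predicted mean position first
    reaches distance ``R`` from the occlusion point, linearly
    interpolating the crossing.  If the mean exits through the straight
    edge or the horizon is exhausted the final direction is projected
    onto the nearest curved-edge endpoint and the result is flagged.
    """
    prev = belief.mean[:2].copy()
    cur_belief = belief
    prev_trace = float(np.trace(cur_belief.cov[:2, :2]))
    for step in range(1, config.max_blind_frames + 1):
        cur_belief = kf_predict(cur_belief, config)
        trace = float(np.trace(cur_belief.cov[:2, :2]))
        if trace < prev_trace - 1e-9:
            raise NumericalStateError("position uncertainty decreased during blind prediction")
        prev_trace = trace
        pos = cur_belief.mean[:2]
        if np.hypot(pos[0], pos[1]) >= occ.radius:
            phi, fb = _crossing_angle(prev, pos, occ.radius)
            return BlindPrediction(
                bin=bin_of_angle(phi, occ), angle=phi, n_steps=step, fallback=fb
            )
        prev = pos.copy()
    # Horizon exhausted: project the final mean direction onto the edge.
    phi = -math.degrees(math.atan2(prev[1], prev[0])) if np.any(prev) else 0.0
    phi = min(max(phi, -90.0), 90.0)
    return BlindPrediction(
        bin=bin_of_angle(phi, occ),
        angle=phi,
        n_steps=config.max_blind_frames,
        fallback=True,
    )


def choose_bin_for_trial(
    traj: ArcTrajectory,
    occ: OccluderGeometry,
    config: KalmanConfig,
    rng: np.random.Generator,
) -> BlindPrediction:
    """Convenience: visible-phase tracking followed by blind choice."""
    belief = run_visible_phase(traj, config, rng)
    return extrapolate_choose_bin(belief, occ, config)


# ---------------------------------------------------------------------------
# Batched simulation


def _gain_schedule(config: KalmanConfig, n_frames: int) -> list[np.ndarray]:
    """Kalman gains for updates 2..n_frames (observation-independent)."""
    f = config.transition_matrix()
    q = config.process_noise()
    h = config.observation_matrix()
    r = config.obs_noise_sd**2 * np.eye(2)
    p = config.initial_covariance()
    gains = []
    for _ in range(n_frames - 1):
        p = f @ p @ f.T + q
        s = h @ p @ h.T + r
        k = p @ h.T @ np.linalg.inv(s)
        gains.append(k)
        ikh = np.eye(6) - k @ h
        p = ikh @ p @ ikh.T + k @ r @ k.T
        p = 0.5 * (p + p.T)
    return gains


def visible_truth(trajectories: list[ArcTrajectory], config: KalmanConfig) -> np.ndarray:
    """True visible-frame positions, shape (n_trials, n_frames, 2)."""
    n_frames = n_visible_frames(trajectories[0], config)
    svals = _visible_arclengths(trajectories[0], config)
    c = np.array([t.curvature for t in trajectories])[:, None]
    a0 = -np.radians(np.array([t.orientation for t in trajectories]))[:, None]
    a = a0 + c * svals[None, :]
    x = (np.sin(a) - np.sin(a0)) / c
    y = -(np.cos(a) - np.cos(a0)) / c
    return np.stack([x, y], axis=-1).reshape(len(trajectories), n_frames, 2)


def simulate_predictive_choices(
    trajectories: list[ArcTrajectory],
    radius: float,
    config: KalmanConfig,
    rng: np.random.Generator,
    occ: OccluderGeometry | None = None,
    truth: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the predictive observer on many trials at once.

    Returns (chosen_bins, predicted_angles), one entry per trajectory.
    All trajectories must share visible length and speed (true of every
    schedule this package generates).  ``truth`` may carry precomputed
    :func:`visible_truth` output to avoid recomputation across repeated
    runs on the same trials.
    """
    if occ is None:
        occ = OccluderGeometry(radius=radius)
    if not trajectories:
        return np.zeros(0, dtype=int), np.zeros(0)
    vis = {(t.visible_length, t.speed) for t in trajectories}
    if len(vis) != 1:
        raise ValueError("batched simulation requires homogeneous visible length/speed")
    n_frames = n_visible_frames(trajectories[0], config)
    n = len(trajectories)

    if truth is None:
        truth = visible_truth(trajectories, config)
    obs = truth + config.obs_noise_sd * rng.standard_normal(truth.shape)

    f = config.transition_matrix()
    gains = _gain_schedule(config, n_frames)
    h = config.observation_matrix()

    means = np.zeros((n, 6))
    means[:, :2] = obs[:, 0]
    for j in range(1, n_frames):
        means = means @ f.T
        innov = obs[:, j] - means @ h.T
        means = means + innov @ gains[j - 1].T

    bins = np.zeros(n, dtype=int)
    angles = np.zeros(n)
    active = np.ones(n, dtype=bool)
    prev = means[:, :2].copy()
    for _ in range(config.max_blind_frames):
        if not active.any():
            break
        means[active] = means[active] @ f.T
        pos = means[:, :2]
        crossed = active & (np.hypot(pos[:, 0], pos[:, 1]) >= radius)
        for i in np.where(crossed)[0]:
            phi, _ = _crossing_angle(prev[i], pos[i], radius)
            angles[i] = phi
            bins[i] = bin_of_angle(phi, occ)
        active &= ~crossed
        prev[active] = pos[active]
    for i in np.where(active)[0]:  # horizon exhausted
        p = prev[i]
        phi = -math.degrees(math.atan2(p[1], p[0])) if np.any(p) else 0.0
        phi = min(max(phi, -90.0), 90.0)
        angles[i] = phi
        bins[i] = bin_of_angle(phi, occ)
    return bins, angles


# ---------------------------------------------------------------------------
# Calibration


DEFAULT_SIGMA_GRID = tuple(np.round(np.arange(0.1, 3.01, 0.1), 2)) + (
    4.0,
    6.0,
    8.0,
    12.0,
)
DEFAULT_Q_GRID = (0.0, 1e3, 1e5, 1e7)


def calibrate_predictive_noise(
    target_accuracy: float,
    schedule,
    base_config: KalmanConfig | None = None,
    sigma_grid=DEFAULT_SIGMA_GRID,
    q_grid=DEFAULT_Q_GRID,
    n_seeds: int = 5,
    seed: int = 0,
    tolerance: float = 0.03,
    distance_anchor: float | None = 1.32,
) -> tuple[KalmanConfig, float, float]:
    """Grid-search (obs noise, process noise) to hit a pre-test accuracy.

    The observer's internal noise constants are not identifiable from
    first principles, so they are anchored to behavior: the primary
    objective is the pre-test accuracy level; among grid points within
    ``tolerance`` of it, ties break toward ``distance_anchor``, the
    behavioral mean absolute bin distance (default 1.32 bins, midway
    between the two training groups' pre-test values).  Several
    (sigma, q) ridges attain the same accuracy with different error
    profiles, so the secondary anchor pins down which one is meant.
    Returns (config, achieved accuracy, mean absolute bin distance).
    """
    if not 0.05 < target_accuracy < 1.0:
        raise ValueError("target accuracy must lie in (0.05, 1)")
    base = base_config or KalmanConfig()
    trials = list(schedule.trials)
    radii = sorted({t.radius for t in trials})
    true_bins = np.array([t.true_bin for t in trials])
    by_radius = {
        r: np.array([i for i, t in enumerate(trials) if t.radius == r]) for r in radii
    }
    trajs_by_radius = {r: [trials[i].trajectory for i in by_radius[r]] for r in radii}
    truth_by_radius = {r: visible_truth(trajs_by_radius[r], base) for r in radii}
    best = None
    achieved: list[float] = []
    for sig in sigma_grid:
        for q in q_grid:
            cfg = replace(base, obs_noise_sd=sig, process_noise_intensity=q)
            accs = []
            dists = []
            for s in range(n_seeds):
                rng = np.random.default_rng((seed, s))
                chosen = np.zeros(len(trials), dtype=int)
                for r in radii:
                    bins, _ = simulate_predictive_choices(
                        trajs_by_radius[r], r, cfg, rng, truth=truth_by_radius[r]
                    )
                    chosen[by_radius[r]] = bins
                accs.append(float(np.mean(chosen == true_bins)))
                dists.append(float(np.mean(np.abs(chosen - true_bins))))
            acc = float(np.mean(accs))
            dist = float(np.mean(dists))
            achieved.append(acc)
            gap = abs(acc - target_accuracy)
            # Lexicographic key: accuracy gap quantized to the tolerance,
            # then distance to the behavioral abs-distance anchor.
            dgap = abs(dist - distance_anchor) if distance_anchor is not None else 0.0
            key = (gap > tolerance, gap if gap > tolerance else 0.0, dgap, gap)
            if best is None or key < best[0]:
                best = (key, cfg, acc, dist)
    assert best is not None
    if abs(best[2] - target_accuracy) > tolerance:
        raise CalibrationError(
            f"target {target_accuracy} unreachable on grid; achieved range "
            f"[{min(achieved):.3f}, {max(achieved):.3f}]"
        )
    return best[1], best[2], best[3]
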