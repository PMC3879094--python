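"""Experiment schedules: test sets, training blocks, transfer blocks.

The reference task has two experiments.  Experiment 1 uses a single
occluder radius (125 px = 4 DVA): a 320-trial pre-test, five training
blocks of 80 feedback trials (either 4 trajectories x 20 repetitions
per block, the "4Traj" group, or 20 trajectories x 4 repetitions, the
"20Traj" group) each followed by an 80-trial no-feedback transfer
block, and a 320-trial post-test.  Experiment 2 adds two occluder
radii (87.5 and 162.5 px) and replaces the test sessions with 600
trials (200 trajectories x 3 radii), two thirds of which reach a
different bin at each radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    ArcTrajectory,
    OccluderGeometry,
    bin_edges,
    bin_of_angle,
    emergence_angle,
    emergence_angles,
    is_legal,
)

__all__ = [
    "ExperimentConfig",
    "TrialSpec",
    "SessionSchedule",
    "ScheduleError",
    "sample_test_set",
    "build_training_set",
    "build_transfer_set",
    "build_exp2_test_set",
    "quadrant_of",
    "schedule_to_frame",
    "schedule_from_frame",
]

PHASES = ("pretest", "training", "transfer", "posttest")
GROUPS = ("4Traj", "20Traj")


class ScheduleError(ValueError):
    """A schedule could not be constructed from the given configuration."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Stimulus-space bounds and session structure for one experiment."""

    experiment: int
    curvature_min: float
    curvature_max: float
    orientation_max: float
    radii: tuple[float, ...]
    training_radius: float
    trained_bins: tuple[int, ...]
    n_test_per_quadrant: int = 80
    n_training_blocks: int = 5
    n_trials_per_block: int = 80
    n_transfer_reps: int = 4
    bin_count: int = 20
    bin_span: float = 9.0

    @classmethod
    def exp1(cls) -> "ExperimentConfig":
        return cls(
            experiment=1,
            curvature_min=0.0016,
            curvature_max=0.0079,
            orientation_max=60.0,
            radii=(125.0,),
            training_radius=125.0,
            trained_bins=(1, 7, 13, 17),
        )

    @classmethod
    def exp2(cls) -> "ExperimentConfig":
        return cls(
            experiment=2,
            curvature_min=0.0016,
            curvature_max=0.0044,
            orientation_max=60.0,
            radii=(87.5, 125.0, 162.5),
            training_radius=125.0,
            trained_bins=(3, 8, 12, 18),
        )

    def occluder(self, radius: float | None = None) -> OccluderGeometry:
        return OccluderGeometry(
            radius=self.training_radius if radius is None else radius,
            bin_count=self.bin_count,
            bin_span=self.bin_span,
        )

    def trajectory_is_legal(self, traj: ArcTrajectory) -> bool:
        return is_legal(
            traj,
            self.radii,
            self.curvature_min,
            self.curvature_max,
            self.orientation_max,
        )


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus presentation."""

    trajectory: ArcTrajectory
    radius: float
    true_bin: int
    phase: str
    block: int
    feedback: bool
    rep: int
    traj_id: int = -1
    different_bins: bool | None = None


@dataclass
class SessionSchedule:
    """An ordered, seeded sequence of trials for one subject session."""

    trials: list[TrialSpec]
    group: str | None
    seed: int | None
    experiment: int
    config: ExperimentConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def quadrant_of(traj: ArcTrajectory) -> int:
    """Sign-quadrant index of (curvature, orientation).

    Fixed enumeration (+,+) -> 1, (+,-) -> 2, (-,+) -> 3, (-,-) -> 4;
    orientation exactly 0 counts as positive.
    """
    kpos = traj.curvature > 0
    tpos = traj.orientation >= 0
    return {(True, True): 1, (True, False): 2, (False, True): 3, (False, False): 4}[
        (kpos, tpos)
    ]


def _sample_box(
    config: ExperimentConfig,
    n: int,
    rng: np.random.Generator,
    kappa_sign: int | None = None,
    theta_sign: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform (kappa, theta) draws from the (signed) legal box."""
    mag = rng.uniform(config.curvature_min, config.curvature_max, size=n)
    if kappa_sign is None:
        ks = rng.choice([-1.0, 1.0], size=n)
    else:
        ks = float(kappa_sign)
    if theta_sign is None:
        theta = rng.uniform(-config.orientation_max, config.orientation_max, size=n)
    elif theta_sign > 0:
        theta = rng.uniform(0.0, config.orientation_max, size=n)
    else:
        theta = rng.uniform(-config.orientation_max, 0.0, size=n)
    return mag * ks, theta


def sample_test_set(
    config: ExperimentConfig,
    n_per_quadrant: int,
    rng: np.random.Generator,
    phase: str = "pretest",
    radius: float | None = None,
) -> SessionSchedule:
    """Random no-feedback test session, balanced over sign quadrants.

    Draws ``n_per_quadrant`` legal trajectories uniformly from each of
    the four (sign kappa, sign theta) quadrants of the stimulus box and
    shuffles the presentation order.
    """
    if n_per_quadrant <= 0:
        raise ScheduleError("n_per_quadrant must be positive")
    r = config.training_radius if radius is None else radius
    occ = config.occluder(r)
    trials: list[TrialSpec] = []
    for ks, ts in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        kappa, theta = _sample_box(config, n_per_quadrant, rng, ks, ts)
        for k, t in zip(kappa, theta):
            traj = ArcTrajectory(curvature=float(k), orientation=float(t))
            if not config.trajectory_is_legal(traj):
                raise ScheduleError(
                    "stimulus box contains illegal trajectories; tighten the bounds"
                )
            trials.append(
                TrialSpec(
                    trajectory=traj,
                    radius=r,
                    true_bin=bin_of_angle(emergence_angle(traj, r), occ),
                    phase=phase,
                    block=0,
                    feedback=False,
                    rep=1,
                )
            )
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    return SessionSchedule(trials=trials, group=None, seed=None, experiment=config.experiment, config=config)


def sample_trajectory_in_bin(
    config: ExperimentConfig,
    target_bin: int,
    rng: np.random.Generator,
    radius: float | None = None,
    central_fraction: float = 1.0 / 3.0,
    batch: int = 20000,
    max_batches: int = 50,
) -> ArcTrajectory:
    """Uniform legal trajectory whose emergence angle falls in the
    central ``central_fraction`` of ``target_bin``.

    Training stimuli are kept away from bin boundaries so that the
    trained exemplars are perceptually well separated from their
    neighbours.  Rejection sampling over the stimulus box.
    """
    r = config.training_radius if radius is None else radius
    occ = config.occluder(r)
    lo, hi = bin_edges(target_bin, occ)
    margin = occ.bin_span * (1.0 - central_fraction) / 2.0
    lo_c, hi_c = lo + margin, hi - margin
    reach = config.orientation_max + np.degrees(
        np.arcsin(config.curvature_max * r / 2.0)
    )
    if lo_c >= reach or hi_c <= -reach:
        raise ScheduleError(
            f"could not place a trajectory in bin {target_bin} within the curvature bounds"
        )
    for _ in range(max_batches):
        kappa, theta = _sample_box(config, batch, rng)
        phi = emergence_angles(kappa, theta, r)
        ok = np.where((phi >= lo_c) & (phi < hi_c))[0]
        if ok.size:
            i = int(ok[0])
            return ArcTrajectory(curvature=float(kappa[i]), orientation=float(theta[i]))
    raise ScheduleError(
        f"could not place a trajectory in bin {target_bin} within the curvature bounds"
    )


def _order_without_triples(
    items: np.ndarray, rng: np.random.Generator, max_tries: int = 500
) -> np.ndarray:
    """Shuffle so no value occupies 3+ consecutive slots (local repair)."""
    arr = rng.permutation(items)
    for _ in range(max_tries):
        bad = np.where((arr[:-2] == arr[1:-1]) & (arr[1:-1] == arr[2:]))[0]
        if bad.size == 0:
            return arr
        i = int(bad[0]) + 2
        j = int(rng.integers(len(arr)))
        arr[i], arr[j] = arr[j], arr[i]
    return rng.permutation(items)  # give up on the constraint, keep uniformity


def reachable_bins(config: ExperimentConfig, central_fraction: float = 1.0 / 3.0) -> list[int]:
    """Bins whose central region is attainable under the curvature bounds.

    The maximum emergence-angle magnitude at the training radius is
    ``orientation_max + arcsin(curvature_max * R / 2)``; under the
    Experiment 1 bounds this grazes +/-90 deg and every bin is
    reachable, but the tighter Experiment 2 curvature cap excludes the
    extreme bins.
    """
    occ = config.occluder()
    reach = config.orientation_max + np.degrees(
        np.arcsin(config.curvature_max * config.training_radius / 2.0)
    )
    margin = occ.bin_span * (1.0 - central_fraction) / 2.0
    out = []
    for b in range(1, config.bin_count + 1):
        lo, hi = bin_edges(b, occ)
        if lo + margin < reach and hi - margin > -reach:
            out.append(b)
    return out


def build_training_pool(
    config: ExperimentConfig, rng: np.random.Generator
) -> list[ArcTrajectory]:
    """Training-trajectory pool, indexable by target bin.

    20 trajectories, bin k at index k-1 where bin k is reachable.  When
    the curvature bounds make a bin unreachable (the extreme bins of
    Experiment 2), the nearest reachable bin is used in its place, so
    the pool always has 20 entries and ``pool[b-1]`` is the trajectory
    trained toward bin b (or its nearest attainable neighbour).
    """
    feasible = reachable_bins(config)
    if not feasible:
        raise ScheduleError("no reachable bins under the configured bounds")
    pool = []
    for b in range(1, config.bin_count + 1):
        target = min(feasible, key=lambda f: abs(f - b))
        pool.append(sample_trajectory_in_bin(config, target, rng))
    return pool


def build_training_set(
    config: ExperimentConfig,
    group: str,
    rng: np.random.Generator,
    pool: list[ArcTrajectory] | None = None,
) -> tuple[list[ArcTrajectory], SessionSchedule]:
    """Training phase: 5 blocks x 80 feedback trials.

    The 20-trajectory pool covers all 20 bins; the 4Traj group sees
    only the four whose true bins are the configured trained bins (20
    presentations per trajectory per block), the 20Traj group sees all
    twenty (4 presentations each).  Block order is a seeded shuffle
    with no trajectory occupying three or more consecutive slots.
    """
    if group not in GROUPS:
        raise ScheduleError(f"group must be one of {GROUPS}")
    if pool is None:
        pool = build_training_pool(config, rng)
    occ = config.occluder()
    r = config.training_radius
    if group == "4Traj":
        shown = [pool[b - 1] for b in config.trained_bins]
    else:
        shown = list(pool)
    reps_per_block = config.n_trials_per_block // len(shown)
    trials: list[TrialSpec] = []
    rep_counter = {id(t): 0 for t in shown}
    for block in range(1, config.n_training_blocks + 1):
        idx = np.repeat(np.arange(len(shown)), reps_per_block)
        idx = _order_without_triples(idx, rng)
        for i in idx:
            traj = shown[int(i)]
            rep_counter[id(traj)] += 1
            trials.append(
                TrialSpec(
                    trajectory=traj,
                    radius=r,
                    true_bin=bin_of_angle(emergence_angle(traj, r), occ),
                    phase="training",
                    block=block,
                    feedback=True,
                    rep=rep_counter[id(traj)],
                    traj_id=pool.index(traj),
                )
            )
    sched = SessionSchedule(
        trials=trials, group=group, seed=None, experiment=config.experiment, config=config
    )
    return pool, sched


def build_transfer_set(
    config: ExperimentConfig,
    rng: np.random.Generator,
    pool: list[ArcTrajectory],
    block: int = 1,
) -> SessionSchedule:
    """One 80-trial no-feedback transfer block: 20 trajectories x 4 reps.

    Composition: the four 4Traj-trained trajectories, four more from
    the 20Traj-only pool, and twelve fresh draws from the stimulus box
    (Experiment 2: the four trained plus sixteen fresh draws).
    """
    occ = config.occluder()
    r = config.training_radius
    trained = [pool[b - 1] for b in config.trained_bins]
    others = [pool[i] for i in range(len(pool)) if (i + 1) not in config.trained_bins]
    if config.experiment == 1:
        extra_pool = [others[i] for i in rng.choice(len(others), size=4, replace=False)]
        n_new = 12
    else:
        extra_pool = []
        n_new = 16
    new: list[ArcTrajectory] = []
    while len(new) < n_new:
        kappa, theta = _sample_box(config, 1, rng)
        traj = ArcTrajectory(curvature=float(kappa[0]), orientation=float(theta[0]))
        if config.trajectory_is_legal(traj):
            new.append(traj)
    chosen = trained + extra_pool + new
    idx = np.repeat(np.arange(len(chosen)), config.n_transfer_reps)
    idx = _order_without_triples(idx, rng)
    counts = {i: 0 for i in range(len(chosen))}
    trials = []
    for i in idx:
        counts[int(i)] += 1
        traj = chosen[int(i)]
        trials.append(
            TrialSpec(
                trajectory=traj,
                radius=r,
                true_bin=bin_of_angle(emergence_angle(traj, r), occ),
                phase="transfer",
                block=block,
                feedback=False,
                rep=counts[int(i)],
                traj_id=pool.index(traj) if traj in pool else -1,
            )
        )
    return SessionSchedule(
        trials=trials, group=None, seed=None, experiment=config.experiment, config=config
    )


def build_exp2_test_set(
    config: ExperimentConfig,
    rng: np.random.Generator,
    phase: str = "pretest",
    n_trajectories: int = 200,
    different_quota_fraction: float = 2.0 / 3.0,
    max_batches: int = 200,
) -> SessionSchedule:
    """600-trial multi-radius test session (200 trajectories x 3 radii).

    At least ``ceil(2/3 * 200)`` of the trajectories reach a pairwise
    different bin at each of the three radii; each trajectory carries a
    flag recording whether it satisfies that property.  Presentation
    order is randomized over all 600 trials.
    """
    if len(config.radii) != 3:
        raise ScheduleError("Experiment 2 requires exactly three radii")
    quota = int(np.ceil(different_quota_fraction * n_trajectories))
    occs = {r: config.occluder(r) for r in config.radii}

    distinct: list[ArcTrajectory] = []
    any_class: list[ArcTrajectory] = []
    for _ in range(max_batches):
        if len(distinct) >= quota and len(distinct) + len(any_class) >= n_trajectories:
            break
        kappa, theta = _sample_box(config, 5000, rng)
        for k, t in zip(kappa, theta):
            traj = ArcTrajectory(curvature=float(k), orientation=float(t))
            if not config.trajectory_is_legal(traj):
                continue
            bins = [
                bin_of_angle(emergence_angle(traj, r), occs[r]) for r in config.radii
            ]
            if len(set(bins)) == 3:
                distinct.append(traj)
            else:
                any_class.append(traj)
    if len(distinct) < quota or len(distinct) + len(any_class) < n_trajectories:
        raise ScheduleError("rejection sampling failed to reach the different-bin quota")
    chosen = distinct[:quota] + (distinct + any_class)[quota:n_trajectories]
    flags = [True] * quota + [
        len({bin_of_angle(emergence_angle(t, r), occs[r]) for r in config.radii}) == 3
        for t in chosen[quota:]
    ]

    trials: list[TrialSpec] = []
    for tid, (traj, flag) in enumerate(zip(chosen, flags)):
        for r in config.radii:
            trials.append(
                TrialSpec(
                    trajectory=traj,
                    radius=r,
                    true_bin=bin_of_angle(emergence_angle(traj, r), occs[r]),
                    phase=phase,
                    block=0,
                    feedback=False,
                    rep=1,
                    traj_id=tid,
                    different_bins=flag,
                )
            )
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    return SessionSchedule(
        trials=trials, group=None, seed=None, experiment=config.experiment, config=config
    )


def build_exp1_session(
    config: ExperimentConfig, group: str, seed: int
) -> tuple[SessionSchedule, list[ArcTrajectory]]:
    """Full Experiment 1 session: pre-test, 5 x (training + transfer), post-test."""
    rng = np.random.default_rng(seed)
    pre = sample_test_set(config, config.n_test_per_quadrant, rng, phase="pretest")
    pool, training = build_training_set(config, group, rng)
    trials = list(pre.trials)
    per_block = {
        b: [t for t in training.trials if t.block == b]
        for b in range(1, config.n_training_blocks + 1)
    }
    for b in range(1, config.n_training_blocks + 1):
        trials.extend(per_block[b])
        trials.extend(build_transfer_set(config, rng, pool, block=b).trials)
    post = sample_test_set(config, config.n_test_per_quadrant, rng, phase="posttest")
    trials.extend(post.trials)
    sched = SessionSchedule(
        trials=trials, group=group, seed=seed, experiment=config.experiment, config=config
    )
    return sched, pool


_SCHEDULE_COLUMNS = [
    "subject_id",
    "group",
    "experiment",
    "phase",
    "block",
    "trial_index",
    "rep",
    "radius_px",
    "curvature_invpx",
    "orientation_deg",
    "true_bin",
    "feedback",
    "traj_id",
]


def schedule_to_frame(schedule: SessionSchedule, subject_id: str = "sim") -> pd.DataFrame:
    """Flatten a schedule into the trial-log table format."""
    rows = []
    for i, t in enumerate(schedule.trials):
        rows.append(
            {
                "subject_id": subject_id,
                "group": schedule.group or "",
                "experiment": schedule.experiment,
                "phase": t.phase,
                "block": t.block,
                "trial_index": i,
                "rep": t.rep,
                "radius_px": t.radius,
                "curvature_invpx": t.trajectory.curvature,
                "orientation_deg": t.trajectory.orientation,
                "true_bin": t.true_bin,
                "feedback": t.feedback,
                "traj_id": t.traj_id,
            }
        )
    return pd.DataFrame(rows, columns=_SCHEDULE_COLUMNS)


def schedule_from_frame(df: pd.DataFrame, config: ExperimentConfig | None = None) -> SessionSchedule:
    """Rebuild a SessionSchedule from a trial-log table."""
    missing = [c for c in _SCHEDULE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ScheduleError(f"trial log missing columns: {missing}")
    trials = []
    for _, row in df.iterrows():
        traj = ArcTrajectory(
            curvature=float(row["curvature_invpx"]),
            orientation=float(row["orientation_deg"]),
        )
        trials.append(
            TrialSpec(
                trajectory=traj,
                radius=float(row["radius_px"]),
                true_bin=int(row["true_bin"]),
                phase=str(row["phase"]),
                block=int(row["block"]),
                feedback=bool(row["feedback"]),
                rep=int(row["rep"]),
                traj_id=int(row.get("traj_id", -1)) if "traj_id" in df.columns else -1,
            )
        )
    group = str(df["group"].iloc[0]) if len(df) else None
    experiment = int(df["experiment"].iloc[0]) if len(df) else 1
    return SessionSchedule(
        trials=trials, group=group or None, seed=None, experiment=experiment, config=config
    )
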