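"""Training-set-size sweep: mapping vs predictive strategy performance.

For each training-set size m in {4, 8, 12, 16, 20}, m trajectories
with emergence bins spread evenly over the 20 response bins are
trained for 2000 trials.  The Q-learning mapping agent learns from
feedback; the Kalman predictive observer runs the same trials without
learning.  Relative performance is the log ratio of percent correct
(terminal window for the learner, whole run for the static observer).
The sign change of the log ratio across the size grid locates the
set-size regime in which each strategy is expected to win.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import OccluderGeometry
from .kalman import KalmanConfig, simulate_predictive_choices
from .qpolicy import PolicyConfig, train_mapping_agent
from .stimuli import ExperimentConfig, sample_trajectory_in_bin

__all__ = [
    "SweepResult",
    "AmbiguousCrossoverError",
    "simulate_sweep",
    "find_crossover",
    "spread_bins",
]

DEFAULT_SET_SIZES = (4, 8, 12, 16, 20)


class AmbiguousCrossoverError(RuntimeError):
    """The log performance ratio changes sign more than once."""

    def __init__(self, intervals: list[tuple[int, int]]):
        self.intervals = intervals
        super().__init__(f"multiple sign flips across the size grid: {intervals}")


@dataclass
class SweepResult:
    """Per-size, per-seed percent-correct outcomes of the sweep."""

    set_sizes: tuple[int, ...]
    percent_correct_mapping: np.ndarray  # (n_sizes, n_seeds)
    percent_correct_predictive: np.ndarray  # (n_sizes, n_seeds)
    n_trials: int
    seeds: tuple[int, ...]

    @property
    def log_ratio(self) -> np.ndarray:
        """ln(mean mapping percent / mean predictive percent) per size."""
        return np.log(
            self.percent_correct_mapping.mean(axis=1)
            / self.percent_correct_predictive.mean(axis=1)
        )


def spread_bins(m: int, n_bins: int = 20, trained_bins: tuple[int, ...] | None = None) -> list[int]:
    """Target emergence bins for a training set of size m.

    Size 4 uses the experiment's trained-bin set when provided; other
    sizes spread evenly over 1..n_bins (round(linspace)).
    """
    if trained_bins is not None and m == len(trained_bins):
        return sorted(trained_bins)
    if m >= n_bins:
        return list(range(1, n_bins + 1))
    return sorted({int(round(b)) for b in np.linspace(1, n_bins, m)})


def _presentation_order(m: int, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced shuffled order of prototype indices over the session."""
    reps = n_trials // m
    order = np.repeat(np.arange(m), reps)
    extra = n_trials - len(order)
    if extra:
        order = np.concatenate([order, rng.choice(m, size=extra, replace=False)])
    return rng.permutation(order)


def simulate_sweep(
    stim_config: ExperimentConfig,
    kalman_config: KalmanConfig,
    policy_config: PolicyConfig,
    seeds=tuple(range(10)),
    set_sizes=DEFAULT_SET_SIZES,
    n_trials: int = 2000,
    terminal_fraction: float = 0.2,
) -> SweepResult:
    """Run the full set-size sweep.

    Per size and seed: sample m trajectories (one per target bin, away
    from bin boundaries), present each equally often in shuffled order
    for ``n_trials`` trials, train the mapping agent with feedback, and
    run the predictive observer over the same trial sequence.  Mapping
    performance is scored on the final ``terminal_fraction`` of trials
    (post-learning); predictive performance over all trials (the
    observer does not learn).
    """
    radius = stim_config.training_radius
    occ = stim_config.occluder()
    n_sizes = len(set_sizes)
    pc_map = np.zeros((n_sizes, len(seeds)))
    pc_pred = np.zeros((n_sizes, len(seeds)))
    for si, m in enumerate(set_sizes):
        bins = spread_bins(m, stim_config.bin_count, stim_config.trained_bins)
        if len(bins) != m:
            raise ValueError(f"could not spread {m} distinct bins")
        for gi, seed in enumerate(seeds):
            rng = np.random.default_rng((seed, m))
            trajs = [sample_trajectory_in_bin(stim_config, b, rng) for b in bins]
            prototypes = np.array([[t.orientation, t.curvature] for t in trajs])
            true_bins = np.array(bins)
            order = _presentation_order(m, n_trials, rng)
            _, choices = train_mapping_agent(
                prototypes, true_bins, order, policy_config, rng
            )
            correct_map = choices == true_bins[order]
            n_term = max(1, int(round(terminal_fraction * n_trials)))
            pc_map[si, gi] = 100.0 * correct_map[-n_term:].mean()

            trial_trajs = [trajs[i] for i in order]
            pred_bins, _ = simulate_predictive_choices(
                trial_trajs, radius, kalman_config, rng, occ=occ
            )
            pc_pred[si, gi] = 100.0 * np.mean(pred_bins == true_bins[order])
    return SweepResult(
        set_sizes=tuple(set_sizes),
        percent_correct_mapping=pc_map,
        percent_correct_predictive=pc_pred,
        n_trials=n_trials,
        seeds=tuple(seeds),
    )


def find_crossover(sweep: SweepResult | None = None, *, log_ratio=None, set_sizes=None) -> float:
    """Set size at which the winning strategy flips.

    With exactly one sign change between adjacent grid sizes a < b the
    crossover is reported as the midpoint (a + b) / 2.  If the mapping
    strategy wins everywhere the result is +inf; if the predictive
    strategy wins everywhere, -inf.  More than one sign change raises
    :class:`AmbiguousCrossoverError` listing every flip interval.
    A log ratio of exactly zero counts as a predictive win (the
    learner must strictly beat the static observer to win).
    """
    if sweep is not None:
        log_ratio = sweep.log_ratio
        set_sizes = sweep.set_sizes
    lr = np.asarray(log_ratio, dtype=float)
    sizes = list(set_sizes)
    wins = lr > 0  # mapping wins
    flips = [
        (sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1) if wins[i] != wins[i + 1]
    ]
    if len(flips) > 1:
        raise AmbiguousCrossoverError(flips)
    if not flips:
        return math.inf if wins.all() else -math.inf
    a, b = flips[0]
    return (a + b) / 2.0
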