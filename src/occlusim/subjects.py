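"""Synthetic subjects: seeded choice logs from specified strategies.

Every downstream analysis (metrics, Bayes-factor classification,
multi-radius variant tests) is exercised on simulated cohorts.  A
subject is a strategy specification:

* ``full_model`` -- samples from the full 20-category extrapolation
  likelihood (truncated-Gaussian angle noise + lapse);
* ``restricted_classifier`` -- samples from the nearest-allowed-bin
  classifier likelihood (optionally with a per-radius bin mapping);
* ``kalman_agent`` / ``q_agent`` -- actually runs the corresponding
  observer trial by trial (the Q agent learns on feedback trials and
  responds greedily elsewhere);
* ``uniform`` -- lapse-only responder (chance performance).

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .choice_models import (
    CategoryPartition,
    ChoiceModelParams,
    PriorGrid,
    bayes_factor,
    classifier_choice_probs,
    exp2_partition,
    full_model_choice_probs,
    marginal_likelihood,
)
from .geometry import OccluderGeometry
from .kalman import KalmanConfig, simulate_predictive_choices
from .metrics import SubjectDataset
from .qpolicy import PolicyConfig, QTable, identify_state, perceive, run_policy_training, select_action
from .stimuli import SessionSchedule

__all__ = [
    "StrategySpec",
    "simulate_subject",
    "simulate_cohort",
    "recovery_experiment",
]

KINDS = (
    "full_model",
    "restricted_classifier",
    "switching_classifier",
    "kalman_agent",
    "q_agent",
    "uniform",
)


@dataclass(frozen=True)
class StrategySpec:
    """How a synthetic subject turns trials into bin choices.

    ``switching_classifier`` is a demo of feedback reinstatement: the
    subject responds as the restricted classifier until it has made
    ``switch_errors`` errors on feedback trials, then reverts to the
    full extrapolation model for the rest of the session.  No
    quantitative switching rule is established empirically, so the
    threshold is a free configuration knob.
    """

    kind: str
    sigma: float = 9.0
    lapse: float = 0.05
    partition: CategoryPartition | None = None
    kalman_config: KalmanConfig | None = None
    policy_config: PolicyConfig | None = None
    switch_errors: int = 3

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.kind in ("restricted_classifier", "switching_classifier") and self.partition is None:
            raise ValueError(f"{self.kind} requires a partition")


def _sample_from_probs(probs: np.ndarray, rng: np.random.Generator) -> int:
    return int(rng.choice(len(probs), p=probs)) + 1


def simulate_subject(
    schedule: SessionSchedule,
    spec: StrategySpec,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> SubjectDataset:
    """One chosen bin per trial of the schedule, per the strategy spec."""
    trials = list(schedule.trials)
    params = ChoiceModelParams(sigma_resp=spec.sigma, lapse=spec.lapse) if spec.kind in (
        "full_model",
        "restricted_classifier",
        "switching_classifier",
    ) else None
    choices: list[int] = []
    if spec.kind == "uniform":
        choices = [int(b) + 1 for b in rng.integers(20, size=len(trials))]
    elif spec.kind == "full_model":
        for t in trials:
            probs = full_model_choice_probs(t.trajectory, t.radius, params)
            choices.append(_sample_from_probs(probs, rng))
    elif spec.kind == "restricted_classifier":
        for t in trials:
            probs = classifier_choice_probs(t.trajectory, spec.partition, t.radius, params)
            choices.append(_sample_from_probs(probs, rng))
    elif spec.kind == "switching_classifier":
        errors = 0
        for t in trials:
            if errors < spec.switch_errors:
                probs = classifier_choice_probs(t.trajectory, spec.partition, t.radius, params)
            else:
                probs = full_model_choice_probs(t.trajectory, t.radius, params)
            c = _sample_from_probs(probs, rng)
            if t.feedback and c != t.true_bin:
                errors += 1
            choices.append(c)
    elif spec.kind == "kalman_agent":
        cfg = spec.kalman_config or KalmanConfig()
        chosen = np.zeros(len(trials), dtype=int)
        radii = sorted({t.radius for t in trials})
        for r in radii:
            idx = [i for i, t in enumerate(trials) if t.radius == r]
            bins, _ = simulate_predictive_choices(
                [trials[i].trajectory for i in idx], r, cfg, rng
            )
            chosen[idx] = bins
        choices = [int(c) for c in chosen]
    elif spec.kind == "q_agent":
        cfg = spec.policy_config or PolicyConfig()
        feedback = [t for t in trials if t.feedback]
        table: QTable | None = None
        if feedback:
            sub = SessionSchedule(
                trials=feedback,
                group=schedule.group,
                seed=schedule.seed,
                experiment=schedule.experiment,
                config=schedule.config,
            )
            table, _, fb_choices = run_policy_training(sub, cfg, rng)
            fb_iter = iter(fb_choices)
        else:
            raise ValueError("q_agent requires a schedule with feedback trials")
        for t in trials:
            if t.feedback:
                choices.append(int(next(fb_iter)))
            else:
                percept = perceive(t.trajectory, cfg, rng)
                state = identify_state(percept, table, cfg)
                choices.append(select_action(table, state, 0.0, rng))
    return SubjectDataset(
        trials=list(zip(trials, choices)),
        subject_id=subject_id,
        group=schedule.group,
        phase=None,
    )


def simulate_cohort(
    n_per_spec: int,
    specs: dict[str, StrategySpec],
    schedules,
    rng: np.random.Generator,
) -> list[tuple[SubjectDataset, str]]:
    """Independent seeded subjects per spec, with ground-truth labels.

    ``schedules`` is either one schedule shared by all subjects or a
    mapping label -> schedule.
    """
    if n_per_spec < 1:
        raise ValueError("n_per_spec must be >= 1")
    out: list[tuple[SubjectDataset, str]] = []
    for label, spec in specs.items():
        sched = schedules[label] if isinstance(schedules, dict) else schedules
        for i in range(n_per_spec):
            ds = simulate_subject(sched, spec, rng, subject_id=f"{label}-{i}")
            out.append((ds, label))
    return out


def recovery_experiment(
    config,
    rng: np.random.Generator,
    n_per_model: int = 20,
    n_trials: int = 320,
    sigma_range: tuple[float, float] = (6.0, 12.0),
    lapse_max: float = 0.1,
    prior_grid: PriorGrid | None = None,
    exp2_sessions: int = 10,
) -> dict:
    """Strategy-recovery report: can the Bayes factor identify the generator?

    Simulates ``n_per_model`` subjects from the full model and from the
    restricted classifier on a test-style session, classifies each by
    the sign of the log Bayes factor, and tabulates the confusion
    counts.  Also runs the multi-radius variant discrimination:
    classifier subjects generated under the fixed-bin and under the
    radius-consistent bin mapping on 600-trial three-radius sessions,
    identified by comparing the two variants' marginal likelihoods.
    """
    from .stimuli import (
        ExperimentConfig,
        build_exp2_test_set,
        build_training_pool,
        sample_test_set,
    )

    exp1: ExperimentConfig = config if config is not None else ExperimentConfig.exp1()
    grid = prior_grid or PriorGrid()
    n_quadrant = max(1, n_trials // 4)
    schedule = sample_test_set(exp1, n_quadrant, rng)
    trained = CategoryPartition.restricted(exp1.trained_bins)

    results = {"n_per_model": n_per_model, "n_trials": 4 * n_quadrant}
    confusion = {("full_model", s): 0 for s in ("predictive", "mapping", "undecided")}
    confusion.update({("restricted_classifier", s): 0 for s in ("predictive", "mapping", "undecided")})
    correct_sign = 0
    for label, kind in (
        ("full_model", "full_model"),
        ("restricted_classifier", "restricted_classifier"),
    ):
        for i in range(n_per_model):
            sigma = rng.uniform(*sigma_range)
            lapse = rng.uniform(0.0, lapse_max)
            spec = StrategySpec(
                kind=kind,
                sigma=float(sigma),
                lapse=float(lapse),
                partition=trained if kind == "restricted_classifier" else None,
            )
            ds = simulate_subject(schedule, spec, rng, subject_id=f"{label}-{i}")
            ev = bayes_factor(ds, exp1.trained_bins, grid)
            confusion[(label, ev.label)] += 1
            want_positive = kind == "restricted_classifier"
            if (ev.log_bayes_factor > 0) == want_positive:
                correct_sign += 1
    results["sign_recovery_fraction"] = correct_sign / (2 * n_per_model)
    results["confusion"] = {f"{k[0]}->{k[1]}": v for k, v in confusion.items()}

    # Multi-radius variant discrimination (Experiment 2 logic).
    if exp2_sessions <= 0:
        results["variant_recovery_fraction"] = None
        return results
    exp2 = ExperimentConfig.exp2()
    pool = build_training_pool(exp2, rng)
    trained_trajs = [pool[b - 1] for b in exp2.trained_bins]
    fixed = exp2_partition(trained_trajs, exp2.radii, exp2.training_radius, "fixed_bins")
    consistent = exp2_partition(
        trained_trajs, exp2.radii, exp2.training_radius, "extrapolation_consistent"
    )
    variant_correct = 0
    variant_total = 0
    sched2 = build_exp2_test_set(exp2, rng)
    for variant_name, part in (("fixed_bins", fixed), ("extrapolation_consistent", consistent)):
        for i in range(exp2_sessions):
            sigma = rng.uniform(*sigma_range)
            lapse = rng.uniform(0.0, lapse_max)
            spec = StrategySpec(
                kind="restricted_classifier",
                sigma=float(sigma),
                lapse=float(lapse),
                partition=part,
            )
            ds = simulate_subject(sched2, spec, rng, subject_id=f"{variant_name}-{i}")
            ml_fixed = marginal_likelihood(ds, fixed, grid)
            ml_cons = marginal_likelihood(ds, consistent, grid)
            guess = "fixed_bins" if ml_fixed > ml_cons else "extrapolation_consistent"
            variant_correct += guess == variant_name
            variant_total += 1
    results["variant_recovery_fraction"] = variant_correct / variant_total
    return results
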