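"""End-to-end pipeline: generate -> calibrate -> sweep -> recover -> report.

:func:`run_pipeline` executes the full analysis with one seed and
emits a JSON-serializable report containing every headline number:
chance-level check, both noise calibrations, the set-size sweep with
its crossover, and the strategy/variant recovery fractions.  Reruns
with the same configuration are identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .io import RunConfig
from .kalman import calibrate_predictive_noise
from .metrics import percent_correct
from .qpolicy import calibrate_policy_noise
from .stimuli import sample_test_set
from .subjects import StrategySpec, recovery_experiment, simulate_subject
from .sweep import AmbiguousCrossoverError, find_crossover, simulate_sweep

__all__ = ["run_pipeline"]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dictionary.

    Stage failures raise with the failing stage named; the partial
    report assembled so far is attached to the exception.
    """
    report: dict = {"config": config.__dict__.copy(), "stages": []}
    stage = "setup"
    try:
        exp = config.experiment_config()
        rng = np.random.default_rng(config.seed)

        stage = "chance-check"
        sched = sample_test_set(exp, exp.n_test_per_quadrant, rng)
        uniform = simulate_subject(
            sched, StrategySpec(kind="uniform"), np.random.default_rng((config.seed, 1))
        )
        report["chance_accuracy"] = percent_correct(uniform)
        report["stages"].append(stage)

        stage = "calibrate-predictive"
        kcfg, kacc, kdist = calibrate_predictive_noise(
            config.target_accuracy, sched, seed=config.seed
        )
        report["kalman_calibration"] = {
            "obs_noise_sd": kcfg.obs_noise_sd,
            "process_noise_intensity": kcfg.process_noise_intensity,
            "accuracy": kacc,
            "mean_abs_distance": kdist,
        }
        report["stages"].append(stage)

        stage = "calibrate-policy"
        pcfg, pacc = calibrate_policy_noise(kacc, sched, seed=config.seed)
        report["policy_calibration"] = {
            "sigma_theta": pcfg.sigma_theta,
            "sigma_kappa": pcfg.sigma_kappa,
            "accuracy": pacc,
        }
        report["stages"].append(stage)

        stage = "sweep"
        res = simulate_sweep(
            exp,
            kcfg,
            pcfg,
            seeds=tuple(range(config.seed, config.seed + config.sweep_seeds)),
            n_trials=config.sweep_trials,
        )
        try:
            crossover = find_crossover(res)
        except AmbiguousCrossoverError as err:
            crossover = None
            report["crossover_ambiguous_intervals"] = err.intervals
        report["sweep"] = {
            "set_sizes": list(res.set_sizes),
            "percent_correct_mapping": res.percent_correct_mapping.mean(axis=1).tolist(),
            "percent_correct_predictive": res.percent_correct_predictive.mean(axis=1).tolist(),
            "log_ratio": res.log_ratio.tolist(),
            "crossover": crossover,
        }
        report["stages"].append(stage)

        stage = "recovery"
        report["recovery"] = recovery_experiment(
            exp,
            np.random.default_rng((config.seed, 2)),
            n_per_model=config.recovery_subjects,
            n_trials=config.recovery_trials,
            exp2_sessions=config.exp2_sessions,
        )
        report["stages"].append(stage)
    except Exception as err:
        err.pipeline_stage = stage  # type: ignore[attr-defined]
        err.partial_report = report  # type: ignore[attr-defined]
        raise
    return report


def run_and_save(config: RunConfig) -> Path:
    """Run the pipeline and write report + resolved config to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = run_pipeline(config)
    config.to_yaml(out / "resolved_config.yaml")
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    return path
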