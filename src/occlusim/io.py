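"""Trial-log and choice-log CSV I/O plus YAML run configuration.

The choice-log format is the trial-log (schedule) format with an
appended ``chosen_bin`` column; both are plain comma-separated UTF-8
with "." decimals.  Reading validates the header and the chosen-bin
range and reports the offending column or row.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .metrics import SubjectDataset
from .stimuli import (
    ExperimentConfig,
    SessionSchedule,
    _SCHEDULE_COLUMNS,
    schedule_from_frame,
    schedule_to_frame,
)

__all__ = [
    "SchemaError",
    "write_schedule_csv",
    "read_schedule_csv",
    "write_choices_csv",
    "read_choices_csv",
    "RunConfig",
]


class SchemaError(ValueError):
    """A CSV file does not match the expected column schema."""


def write_schedule_csv(schedule: SessionSchedule, path, subject_id: str = "sim") -> Path:
    path = Path(path)
    schedule_to_frame(schedule, subject_id=subject_id).to_csv(path, index=False)
    return path


def read_schedule_csv(path, config: ExperimentConfig | None = None) -> SessionSchedule:
    df = pd.read_csv(path)
    missing = [c for c in _SCHEDULE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise SchemaError(f"schedule file missing columns: {missing}")
    return schedule_from_frame(df, config)


def write_choices_csv(dataset: SubjectDataset, path) -> Path:
    path = Path(path)
    sched = SessionSchedule(
        trials=[t for t, _ in dataset.trials],
        group=dataset.group,
        seed=None,
        experiment=1,
        config=None,
    )
    df = schedule_to_frame(sched, subject_id=dataset.subject_id)
    df["chosen_bin"] = [c for _, c in dataset.trials]
    df.to_csv(path, index=False)
    return path


def read_choices_csv(path, config: ExperimentConfig | None = None) -> SubjectDataset:
    df = pd.read_csv(path)
    required = [c for c in _SCHEDULE_COLUMNS[:-1]] + ["chosen_bin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"choice file missing columns: {missing}")
    bad = df.index[(df["chosen_bin"] < 1) | (df["chosen_bin"] > 20)]
    if len(bad):
        raise SchemaError(f"chosen_bin outside 1..20 at row {int(bad[0])}")
    sched = schedule_from_frame(df, config)
    subject_id = str(df["subject_id"].iloc[0]) if len(df) else "sim"
    group = str(df["group"].iloc[0]) if len(df) and str(df["group"].iloc[0]) != "nan" else None
    return SubjectDataset(
        trials=list(zip(sched.trials, (int(c) for c in df["chosen_bin"]))),
        subject_id=subject_id,
        group=group or None,
    )


@dataclass
class RunConfig:
    """Serializable end-to-end pipeline configuration."""

    experiment: int = 1
    group: str = "4Traj"
    seed: int = 0
    target_accuracy: float = 0.25
    sweep_seeds: int = 10
    sweep_trials: int = 2000
    recovery_subjects: int = 20
    recovery_trials: int = 320
    exp2_sessions: int = 10
    out_dir: str = "results"

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig.exp1() if self.experiment == 1 else ExperimentConfig.exp2()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path
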