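"""Behavioral summary statistics for bin-choice datasets.

The unit of analysis is a :class:`SubjectDataset`: one subject's
aligned (trial, chosen bin) pairs for a phase.  Metrics mirror the
standard descriptive battery for this task: percent correct, mean
absolute and signed bin distance (signed distances oriented so that
negative values mean undershooting the deflection, as if curvature had
been underestimated), per-true-bin choice spread ("confusability"),
choice histograms and the two-sample Kolmogorov-Smirnov statistic
between chosen-bin and true-bin distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .stimuli import TrialSpec

__all__ = [
    "SubjectDataset",
    "UndefinedMetricError",
    "percent_correct",
    "bin_distances",
    "confusability",
    "ks_two_sample",
    "choice_histogram",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given dataset (e.g. empty)."""


@dataclass
class SubjectDataset:
    """Aligned (trial, chosen bin) pairs for one subject and phase."""

    trials: list[tuple[TrialSpec, int]]
    subject_id: str = "sim"
    group: str | None = None
    phase: str | None = None

    def __post_init__(self) -> None:
        for _, c in self.trials:
            if not 1 <= int(c) <= 20:
                raise ValueError(f"chosen bin {c} outside 1..20")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def true_bins(self) -> np.ndarray:
        return np.array([t.true_bin for t, _ in self.trials], dtype=int)

    @property
    def chosen_bins(self) -> np.ndarray:
        return np.array([c for _, c in self.trials], dtype=int)

    @property
    def curvatures(self) -> np.ndarray:
        return np.array([t.trajectory.curvature for t, _ in self.trials])

    def subset(self, phase: str) -> "SubjectDataset":
        return SubjectDataset(
            trials=[(t, c) for t, c in self.trials if t.phase == phase],
            subject_id=self.subject_id,
            group=self.group,
            phase=phase,
        )


def _require_nonempty(dataset: SubjectDataset) -> None:
    if len(dataset) == 0:
        raise UndefinedMetricError("metric undefined on an empty dataset")


def percent_correct(dataset: SubjectDataset) -> float:
    """Fraction of trials whose chosen bin equals the true bin."""
    _require_nonempty(dataset)
    return float(np.mean(dataset.chosen_bins == dataset.true_bins))


def bin_distances(dataset: SubjectDataset) -> tuple[float, float]:
    """(mean absolute, signed mean) bin distance between chosen and true.

    The signed distance orients each trial so that a response short of
    the full curvature deflection counts as negative ("undershoot, as
    if underestimating curvature").  Positive stimulus curvature
    deflects toward lower bin numbers, so the orientation sign is
    ``-sign(curvature)``.
    """
    _require_nonempty(dataset)
    diff = dataset.chosen_bins - dataset.true_bins
    sign = -np.sign(dataset.curvatures)
    return float(np.mean(np.abs(diff))), float(np.mean(sign * diff))


def confusability(dataset: SubjectDataset, method: str = "sd", span_coverage: float = 0.9) -> float:
    """Spread of chosen bins around each true bin, in bins.

    ``method="sd"`` (default): the standard deviation of chosen bins
    is computed for every true bin with at least two trials and the
    mean over those true bins is returned.  ``method="span"``: the
    central span covering ``span_coverage`` of the choices replaces
    the SD.  Larger values mean the subject accepted a wider range of
    responses for the same stimulus class -- higher confusability.
    """
    _require_nonempty(dataset)
    true = dataset.true_bins
    chosen = dataset.chosen_bins
    spreads = []
    for b in np.unique(true):
        ch = chosen[true == b]
        if len(ch) < 2:
            continue
        if method == "sd":
            spreads.append(float(np.std(ch)))
        elif method == "span":
            lo = np.quantile(ch, (1 - span_coverage) / 2)
            hi = np.quantile(ch, 1 - (1 - span_coverage) / 2)
            spreads.append(float(hi - lo))
        else:
            raise ValueError("method must be 'sd' or 'span'")
    if not spreads:
        raise UndefinedMetricError("no true bin has two or more trials")
    return float(np.mean(spreads))


def ks_two_sample(choices_a, choices_b) -> float:
    """Two-sample Kolmogorov-Smirnov D statistic between bin samples."""
    a = np.asarray(choices_a)
    b = np.asarray(choices_b)
    if a.size == 0 or b.size == 0:
        raise UndefinedMetricError("KS statistic undefined for empty samples")
    return float(ks_2samp(a, b, method="asymp").statistic)


def choice_histogram(dataset: SubjectDataset, n_bins: int = 20) -> np.ndarray:
    """Counts of chosen bins 1..n_bins (sums to the trial count)."""
    counts = np.zeros(n_bins, dtype=int)
    for c in dataset.chosen_bins:
        counts[c - 1] += 1
    return counts


def summarize(dataset: SubjectDataset) -> dict:
    """All scalar metrics in one dictionary (for CSV/JSON reports)."""
    absd, signed = bin_distances(dataset)
    out = {
        "subject_id": dataset.subject_id,
        "group": dataset.group,
        "phase": dataset.phase,
        "n_trials": len(dataset),
        "percent_correct": percent_correct(dataset),
        "mean_abs_distance": absd,
        "signed_mean_distance": signed,
        "ks_d_vs_true": ks_two_sample(dataset.chosen_bins, dataset.true_bins),
    }
    try:
        out["confusability"] = confusability(dataset)
    except UndefinedMetricError:
        out["confusability"] = float("nan")
    return out
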