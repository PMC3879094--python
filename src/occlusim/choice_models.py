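"""Likelihood models of bin-choice data and Bayes-factor classification.

Two generative accounts of a subject's bin choices are compared:

* the **full 20-category extrapolation model** -- the subject estimates
  the trajectory, extrapolates to an emergence angle, and responds
  with the bin containing a noisy version of that angle;
* the **restricted-category classifier** -- the subject only ever
  considers a small set of allowed bins (the trained ones) and assigns
  the noisy emergence angle to the nearest allowed bin's center.

Both models share two parameters: an effective emergence-angle noise
SD ``sigma`` (degrees) and a lapse rate ``lapse`` spreading uniform
mass over all 20 bins so that no observed choice has zero probability.
The trajectory-to-bin map factors through the emergence angle, so the
2-D Gaussian category structure over (orientation, curvature) is
collapsed to its 1-D image over the angle.

Model evidence is a log-mean-exp over a fixed uniform parameter grid
(a deterministic, reproducible marginalization); the log Bayes factor
is positive when the restricted classifier fits better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .geometry import ArcTrajectory, OccluderGeometry, emergence_angle

__all__ = [
    "ChoiceModelParams",
    "CategoryPartition",
    "ModelEvidence",
    "PriorGrid",
    "full_model_choice_probs",
    "classifier_choice_probs",
    "log_likelihood",
    "marginal_likelihood",
    "bayes_factor",
    "exp2_predicted_bins",
]

#: log Bayes factor magnitude regarded as strong evidence (natural log)
DECISION_THRESHOLD = 3.0


@dataclass(frozen=True)
class ChoiceModelParams:
    """Shared parameters of both choice models."""

    sigma_resp: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_resp > 0:
            raise ValueError("sigma_resp must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")


@dataclass(frozen=True)
class CategoryPartition:
    """Which response bins a model considers, possibly per occluder radius.

    ``kind`` is ``"full20"`` (all bins) or ``"restricted"`` (exactly the
    allowed bins).  ``per_radius`` optionally maps radius -> allowed-bin
    tuple for the multi-radius variants; when present it overrides
    ``allowed_bins`` at those radii.
    """

    kind: str
    allowed_bins: tuple[int, ...]
    per_radius: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("full20", "restricted"):
            raise ValueError("kind must be 'full20' or 'restricted'")
        if self.kind == "full20" and len(self.allowed_bins) != 20:
            raise ValueError("full20 partition must allow all 20 bins")
        if not self.allowed_bins:
            raise ValueError("allowed bin set must be non-empty")

    @classmethod
    def full(cls, n_bins: int = 20) -> "CategoryPartition":
        return cls(kind="full20", allowed_bins=tuple(range(1, n_bins + 1)))

    @classmethod
    def restricted(cls, bins, per_radius: dict | None = None) -> "CategoryPartition":
        return cls(kind="restricted", allowed_bins=tuple(sorted(bins)), per_radius=per_radius)

    def allowed_for(self, radius: float) -> tuple[int, ...]:
        if self.per_radius is not None:
            for r, bins in self.per_radius.items():
                if abs(r - radius) < 1e-9:
                    return tuple(sorted(bins))
        return self.allowed_bins


@dataclass(frozen=True)
class ModelEvidence:
    """Log marginal likelihoods of the two models and their contrast."""

    log_ml_full: float
    log_ml_restricted: float

    @property
    def log_bayes_factor(self) -> float:
        """Positive favors the restricted-category classifier."""
        return self.log_ml_restricted - self.log_ml_full

    @property
    def label(self) -> str:
        if self.log_bayes_factor > DECISION_THRESHOLD:
            return "mapping"
        if self.log_bayes_factor < -DECISION_THRESHOLD:
            return "predictive"
        return "undecided"


@dataclass(frozen=True)
class PriorGrid:
    """Uniform marginalization grid over (sigma, lapse)."""

    sigmas: tuple[float, ...] = tuple(float(s) for s in range(1, 46))
    lapses: tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.5001, 0.025), 3))

    def __len__(self) -> int:
        return len(self.sigmas) * len(self.lapses)


def _bin_edges_array(occ: OccluderGeometry) -> np.ndarray:
    return -90.0 + occ.bin_span * np.arange(occ.bin_count + 1)


def _truncnorm_bin_mass(
    phi: np.ndarray, sigma: float, occ: OccluderGeometry
) -> np.ndarray:
    """Mass of a [-90, 90]-truncated Normal(phi, sigma) in each bin.

    Shape: (..., n_bins); rows sum to 1.
    """
    edges = _bin_edges_array(occ)
    phi = np.asarray(phi, dtype=float)[..., None]
    cdf = norm.cdf((edges - phi) / sigma)
    mass = np.diff(cdf, axis=-1)
    z = cdf[..., -1] - cdf[..., 0]
    return mass / z[..., None]


def full_model_choice_probs(
    traj: ArcTrajectory,
    radius: float,
    params: ChoiceModelParams,
    occ: OccluderGeometry | None = None,
) -> np.ndarray:
    """Choice distribution of the full 20-category extrapolation model.

    A truncated Gaussian over the emergence angle integrated per bin,
    mixed with a uniform lapse.
    """
    if occ is None:
        occ = OccluderGeometry(radius=radius)
    phi = emergence_angle(traj, radius)
    mass = _truncnorm_bin_mass(np.array(phi), params.sigma_resp, occ)
    return (1.0 - params.lapse) * mass + params.lapse / occ.bin_count


def _classifier_cell_masses(
    phi: np.ndarray, sigma: float, centers: np.ndarray, occ: OccluderGeometry
) -> np.ndarray:
    """P(noisy angle assigned to each allowed center), truncated to the edge.

    Cell boundaries are midpoints between consecutive allowed centers;
    the outer cells extend to the occluder edge, so the result rows sum
    to 1.  Shape: (..., n_allowed).
    """
    mids = 0.5 * (centers[:-1] + centers[1:])
    bounds = np.concatenate([[-90.0], mids, [90.0]])
    phi = np.asarray(phi, dtype=float)[..., None]
    cdf = norm.cdf((bounds - phi) / sigma)
    mass = np.diff(cdf, axis=-1)
    z = cdf[..., -1] - cdf[..., 0]
    return mass / z[..., None]


def classifier_choice_probs(
    traj: ArcTrajectory,
    partition: CategoryPartition,
    radius: float,
    params: ChoiceModelParams,
    occ: OccluderGeometry | None = None,
) -> np.ndarray:
    """Choice distribution of the restricted-category classifier.

    A noisy emergence angle is deterministically assigned to the
    nearest allowed bin's center; non-allowed bins receive only lapse
    mass.
    """
    if partition.kind != "restricted":
        raise ValueError("classifier_choice_probs requires a restricted partition")
    if occ is None:
        occ = OccluderGeometry(radius=radius)
    allowed = partition.allowed_for(radius)
    centers = np.array([-90.0 + occ.bin_span * (b - 0.5) for b in allowed])
    phi = emergence_angle(traj, radius)
    mass = _classifier_cell_masses(np.array(phi), params.sigma_resp, centers, occ)
    probs = np.full(occ.bin_count, params.lapse / occ.bin_count)
    for j, b in enumerate(allowed):
        probs[b - 1] += (1.0 - params.lapse) * mass[j]
    return probs


def _dataset_angles_radii_choices(dataset):
    phis = np.array([emergence_angle(t.trajectory, t.radius) for t, _ in dataset])
    radii = np.array([t.radius for t, _ in dataset])
    chosen = np.array([c for _, c in dataset], dtype=int)
    return phis, radii, chosen


def _as_trial_pairs(dataset):
    """Accept either a SubjectDataset or an iterable of (TrialSpec, chosen)."""
    if hasattr(dataset, "trials"):
        return list(dataset.trials)
    return list(dataset)


def _chosen_prob_table(
    pairs, partition: CategoryPartition, sigmas: np.ndarray, occ: OccluderGeometry
) -> np.ndarray:
    """Non-lapse probability of each observed choice, per sigma.

    Shape (n_sigmas, n_trials): the truncated-Gaussian (full model) or
    nearest-center-cell (classifier) mass of the chosen bin.
    """
    phis, radii, chosen = _dataset_angles_radii_choices(pairs)
    n_s, n_t = len(sigmas), len(pairs)
    out = np.zeros((n_s, n_t))
    for r in np.unique(radii):
        sel = radii == r
        ph = phis[sel]
        ch = chosen[sel]
        if partition.kind == "full20":
            for i, s in enumerate(sigmas):
                mass = _truncnorm_bin_mass(ph, s, occ)
                out[i, sel] = mass[np.arange(len(ph)), ch - 1]
        else:
            allowed = partition.allowed_for(float(r))
            centers = np.array([-90.0 + occ.bin_span * (b - 0.5) for b in allowed])
            col = {b: j for j, b in enumerate(allowed)}
            idx = np.array([col.get(c, -1) for c in ch])
            for i, s in enumerate(sigmas):
                mass = _classifier_cell_masses(ph, s, centers, occ)
                vals = np.where(idx >= 0, mass[np.arange(len(ph)), idx], 0.0)
                out[i, sel] = vals
    return out


def log_likelihood(
    dataset,
    partition: CategoryPartition,
    params: ChoiceModelParams,
    occ: OccluderGeometry | None = None,
) -> float:
    """Sum of log choice probabilities of the observed bins.

    Returns -inf (with a warning) when ``lapse`` is 0 and a choice lies
    outside the model's support.
    """
    pairs = _as_trial_pairs(dataset)
    if not pairs:
        return 0.0
    if occ is None:
        occ = OccluderGeometry(radius=pairs[0][0].radius)
    chosen = np.array([c for _, c in pairs], dtype=int)
    if np.any((chosen < 1) | (chosen > occ.bin_count)):
        raise ValueError("chosen bins must lie in 1..20")
    g = _chosen_prob_table(pairs, partition, np.array([params.sigma_resp]), occ)[0]
    p = (1.0 - params.lapse) * g + params.lapse / occ.bin_count
    if np.any(p <= 0):
        import warnings

        warnings.warn("choice outside model support with zero lapse; log-likelihood is -inf")
        return float("-inf")
    return float(np.sum(np.log(p)))


def marginal_likelihood(
    dataset,
    partition: CategoryPartition,
    prior_grid: PriorGrid | None = None,
    occ: OccluderGeometry | None = None,
) -> float:
    """Log marginal likelihood under a uniform grid prior on (sigma, lapse).

    Computed as log-mean-exp of the per-grid-point log likelihoods;
    deterministic for a fixed grid.
    """
    grid = prior_grid or PriorGrid()
    pairs = _as_trial_pairs(dataset)
    if not pairs:
        return 0.0
    if occ is None:
        occ = OccluderGeometry(radius=pairs[0][0].radius)
    sigmas = np.array(grid.sigmas, dtype=float)
    lapses = np.array(grid.lapses, dtype=float)
    g = _chosen_prob_table(pairs, partition, sigmas, occ)  # (n_sig, n_trials)
    with np.errstate(divide="ignore"):
        # (n_sig, n_lapse, n_trials) -> sum over trials
        p = (1.0 - lapses)[None, :, None] * g[:, None, :] + (
            lapses[None, :, None] / occ.bin_count
        )
        ll = np.sum(np.log(p), axis=-1)
    flat = ll.ravel()
    if np.all(np.isneginf(flat)):
        raise RuntimeError("all prior-grid points have zero likelihood")
    return float(logsumexp(flat) - np.log(flat.size))


def bayes_factor(
    dataset,
    trained_bins,
    prior_grid: PriorGrid | None = None,
    occ: OccluderGeometry | None = None,
    restricted_partition: CategoryPartition | None = None,
) -> ModelEvidence:
    """Evidence contrast: restricted classifier vs full extrapolation model.

    Positive log Bayes factors favor the classifier ("mapping"
    strategy); an empty dataset carries no evidence (log BF = 0).
    """
    pairs = _as_trial_pairs(dataset)
    if not pairs:
        return ModelEvidence(log_ml_full=0.0, log_ml_restricted=0.0)
    restricted = restricted_partition or CategoryPartition.restricted(trained_bins)
    full = CategoryPartition.full()
    return ModelEvidence(
        log_ml_full=marginal_likelihood(pairs, full, prior_grid, occ),
        log_ml_restricted=marginal_likelihood(pairs, restricted, prior_grid, occ),
    )


def exp2_predicted_bins(
    trained_trajectories: list[ArcTrajectory],
    radius: float,
    variant: str,
    training_radius: float = 125.0,
) -> tuple[int, ...]:
    """Allowed-bin set of the two multi-radius classifier variants.

    ``fixed_bins``: the numbered bins reinforced during training (the
    trained trajectories' emergence bins at the training radius) are
    reused unchanged at every radius.  ``extrapolation_consistent``:
    the bins the trained trajectories geometrically emerge into at the
    given radius (identical to the trained set at the training radius).
    """
    from .geometry import bin_of_angle

    if variant == "fixed_bins":
        radius = training_radius
    elif variant != "extrapolation_consistent":
        raise ValueError("variant must be 'fixed_bins' or 'extrapolation_consistent'")
    occ = OccluderGeometry(radius=radius)
    return tuple(
        sorted({bin_of_angle(emergence_angle(t, radius), occ) for t in trained_trajectories})
    )


def exp2_partition(
    trained_trajectories: list[ArcTrajectory],
    radii,
    training_radius: float,
    variant: str,
) -> CategoryPartition:
    """Restricted partition for a multi-radius session under a variant.

    ``fixed_bins`` uses the trained-bin set (the bins at the training
    radius) at every radius; ``extrapolation_consistent`` recomputes
    the emergence bins of the trained trajectories at each radius.
    """
    base = exp2_predicted_bins(
        trained_trajectories, training_radius, "extrapolation_consistent"
    )
    if variant == "fixed_bins":
        per_radius = {float(r): base for r in radii}
    elif variant == "extrapolation_consistent":
        per_radius = {
            float(r): exp2_predicted_bins(
                trained_trajectories, float(r), "extrapolation_consistent"
            )
            for r in radii
        }
    else:
        raise ValueError("variant must be 'fixed_bins' or 'extrapolation_consistent'")
    return CategoryPartition.restricted(base, per_radius=per_radius)
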