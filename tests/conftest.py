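import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from occlusim.geometry import OccluderGeometry
from occlusim.stimuli import ExperimentConfig, sample_test_set


@pytest.fixture
def occ125() -> OccluderGeometry:
    return OccluderGeometry(radius=125.0)


@pytest.fixture
def exp1() -> ExperimentConfig:
    return ExperimentConfig.exp1()


@pytest.fixture
def exp2() -> ExperimentConfig:
    return ExperimentConfig.exp2()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def pretest_schedule():
    """A 320-trial pre-test schedule shared across expensive tests."""
    return sample_test_set(
        ExperimentConfig.exp1(), 80, np.random.default_rng(7), phase="pretest"
    )


def random_legal_trajectories(n, rng, curvature_max=0.0079, radius=None):
    """(kappa, theta) arrays uniform over the Experiment-1-style box."""
    kappa = rng.uniform(0.0016, curvature_max, size=n) * rng.choice([-1, 1], size=n)
    theta = rng.uniform(-60.0, 60.0, size=n)
    return kappa, theta
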