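"""Shared fixtures.

The expensive trained models (bead regressor, siamese network, the
end-to-end classification runs) are session-scoped so unit tests and the
acceptance suite score the same artifacts instead of retraining.
"""

import warnings

import numpy as np
import pytest

from flowpheno import experiments
from flowpheno.synth import CellPhantom, OpticalModel


def pytest_configure(config):
    warnings.simplefilter("ignore", UserWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def optics():
    return OpticalModel()


@pytest.fixture()
def centered_round(optics):
    return CellPhantom("round", {"radius": 3.0}, 0.0, (23.5, 23.5), 0.0)


# ------------------------------------------------------- heavy artifacts

@pytest.fixture(scope="session")
def bead_recovery():
    """Bead z-regression recovery on the default synthetic preset."""
    return experiments.bead_recovery_experiment(seed=0)


@pytest.fixture(scope="session")
def bead_sign_control():
    """Negative control: symmetric blur (asym_strength = 0)."""
    return experiments.bead_recovery_experiment(seed=0, asym=0.0,
                                                max_epochs=25)


@pytest.fixture(scope="session")
def siamese_recovery():
    """Siamese z-distance recovery on heterogeneous cell stacks."""
    return experiments.siamese_recovery_experiment(seed=0)


@pytest.fixture(scope="session")
def classification_runs():
    """End-to-end runs (simulate -> detect -> FactorVAE -> classify),
    one per seed."""
    return [experiments.classification_experiment(seed=s) for s in (0, 1, 2)]


@pytest.fixture(scope="session")
def detector_stats():
    return experiments.detector_performance(seed=0, n_frames=500)


@pytest.fixture(scope="session")
def disentangle_ab():
    return experiments.disentanglement_experiment(seeds=(0, 1, 2))
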