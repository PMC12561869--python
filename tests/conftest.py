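import numpy as np
import pytest

from sleepstager.synth import StageSignalModel, make_dataset


@pytest.fixture(scope="session")
def default_signal_model():
    return StageSignalModel()


@pytest.fixture(scope="session")
def small_cohort():
    """5 synthetic subjects x 60 epochs, normalized; shared across tests."""
    return make_dataset(n_subjects=5, epochs_per_subject=60, seed=123)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(0)
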