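import numpy as np
import pytest

from chirpefr import Epochs, SimParams, StimulusSpec


@pytest.fixture(scope="session")
def narrowband() -> StimulusSpec:
    return StimulusSpec.narrowband()


@pytest.fixture(scope="session")
def wideband() -> StimulusSpec:
    return StimulusSpec.wideband()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_epochs(data, sample_rate=512.0, t0_index=None, labels=None) -> Epochs:
    data = np.asarray(data, dtype=float)
    if t0_index is None:
        t0_index = data.shape[-1] // 2
    return Epochs(data=data, sample_rate=sample_rate, t0_index=t0_index,
                  channel_labels=labels or [])


@pytest.fixture(scope="session")
def noiseless_params() -> SimParams:
    """Small noiseless simulation, fast enough for unit tests."""
    return SimParams(n_trials=40, kappa=2.0, noise_amplitude=0.0, seed=11)
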