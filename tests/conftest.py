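import numpy as np
import pytest

from cltnet.data_io import EEGTrialSet, zscore_normalize
from cltnet.synthetic import make_fixture


@pytest.fixture(scope="session")
def tiny_set() -> EEGTrialSet:
    """Small 2-class, 3-channel, 500-sample set for fast structural tests."""
    return zscore_normalize(make_fixture("tiny-2class"))


@pytest.fixture(scope="session")
def strong_erd_set() -> EEGTrialSet:
    """Strongly separable 2-class set (200 trials/class) for learning tests."""
    return zscore_normalize(make_fixture("strong-erd-2class"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_trialset(rng, n_trials=10, n_channels=3, n_samples=64, n_classes=2,
                    fs=250.0) -> EEGTrialSet:
    return EEGTrialSet(
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        labels=rng.integers(0, n_classes, size=n_trials),
        fs=fs,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        class_names=[f"class{i}" for i in range(n_classes)],
    )
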