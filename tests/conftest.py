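import numpy as np
import pytest

from wavecog import SynthConfig, build_feature_matrices, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial two-class set used across modules."""
    cfg = SynthConfig(
        n_epochs_per_class=20, n_channels=4, epoch_len=512, seed=7
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    return build_feature_matrices(small_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
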