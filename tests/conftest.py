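import numpy as np
import pytest

from repcount import SyntheticConfig, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    # few channels and short gaps keep the series small and tests fast
    return SyntheticConfig(
        channels=4,
        n_instances=12,
        gap_duration_s=(0.5, 1.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_corpus(small_cfg):
    return generate_corpus(
        small_cfg, n_sequences=24, n_test=4, val_fraction=0.1, rng=7, replication=2
    )
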