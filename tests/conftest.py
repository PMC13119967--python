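import numpy as np
import pytest

from sts_neurokin import GeneratorConfig, generate_trial


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free stated world: deterministic trajectories, no artifacts."""
    return GeneratorConfig(marker_noise_sd_m=0.0, emg_noise_sd=0.0,
                           spike_rate=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    return generate_trial(clean_config, "S01", "free_arms")


@pytest.fixture(scope="session")
def clean_block(clean_config):
    """One recording holding five consecutive repetitions."""
    return generate_trial(clean_config, "S01", "free_arms", n_repetitions=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
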