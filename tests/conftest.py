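import numpy as np
import pytest

from idrscan.profile import DisorderThresholds
from idrscan.synthetic import SyntheticConfig, synthesize_proteome


@pytest.fixture
def rng():
    return np.random.default_rng(20220418)


@pytest.fixture
def thresholds():
    return DisorderThresholds()


@pytest.fixture(scope="session")
def noiseless_proteome():
    """Small synthetic proteome with exact (noise-free) score tracks."""
    config = SyntheticConfig(n_proteins=120, score_noise_sd=0.0, seed=7)
    records, tracks, truths = synthesize_proteome(config)
    return config, records, tracks, truths


@pytest.fixture(scope="session")
def noisy_proteome():
    """Synthetic proteome at the default score-noise level (sd 0.1)."""
    config = SyntheticConfig(n_proteins=200, score_noise_sd=0.1, seed=11)
    records, tracks, truths = synthesize_proteome(config)
    return config, records, tracks, truths
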