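import numpy as np
import pytest

from irpnn import Spectrum, SyntheticConfig, TissueClass, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_config():
    """Generator config with every random term switched off."""
    return SyntheticConfig(noise_sd=0.0, amplitude_jitter=0.0, baseline_slope_sd=0.0)


@pytest.fixture(scope="session")
def default_cohort():
    """The full 440-sample synthetic cohort at seed 1 (shared, read-only)."""
    return simulate_cohort(SyntheticConfig(seed=1))


@pytest.fixture
def random_spectrum(rng):
    n = 101
    wn = 2000.0 - 2.0 * np.arange(n)
    return Spectrum(wn, rng.normal(0.3, 0.1, n), sample_id="rand", label=TissueClass.NORMAL)
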