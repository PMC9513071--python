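import numpy as np
import pytest

from bcmotion import synth


@pytest.fixture(scope="session")
def rds_rf():
    """A calibrated center-surround RF with a delayed strong surround."""
    return synth.make_rf(synth.SyntheticRFParams())


@pytest.fixture(scope="session")
def surround_free_rf():
    """A separable (surround-free) RF: no space-time asymmetry."""
    return synth.make_rf(synth.SyntheticRFParams(surround_strength=0.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
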