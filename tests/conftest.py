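import numpy as np
import pytest

from spotlight3d import SynthConfig, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sample():
    """A small synthetic paired volume shared by read-only tests."""
    return generate_sample(
        SynthConfig(shape=(32, 32, 32), n_nuclei=3, radius_range=(3.0, 4.5), seed=7)
    )
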