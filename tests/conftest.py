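import numpy as np
import pytest

from ctwaist import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noise-free default torso phantom with its ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
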