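import numpy as np
import pytest

from bwseg import PhantomSpec, Radiograph, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_radiograph(rng):
    return Radiograph(rng.random((40, 50)), id="random")


@pytest.fixture(scope="session")
def level_phantom():
    """Noise-free, unrotated 4+4 phantom with its ground truth."""
    return generate_phantom(PhantomSpec(rotation_deg=0.0, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def tilted_phantom():
    """Default-noise 4+4 phantom tilted by -7 degrees."""
    return generate_phantom(PhantomSpec(rotation_deg=-7.0, seed=7))
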