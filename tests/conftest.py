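import numpy as np
import pytest

from mammoseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_sample():
    """One deterministic 128^2 phantom with two masses."""
    return generate_phantom(PhantomConfig(image_size=128, n_masses=2, seed=11))


@pytest.fixture(scope="session")
def phantom_batch():
    """Ten small deterministic phantoms with one mass each."""
    return [generate_phantom(PhantomConfig(image_size=128, n_masses=1, seed=100 + i))
            for i in range(10)]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
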