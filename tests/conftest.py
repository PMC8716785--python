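import numpy as np
import pytest

from cmbforge.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small deterministic phantom with vessels and noise."""
    return generate_phantom(PhantomConfig(shape=(48, 48, 32), n_vessels=3, seed=11))


@pytest.fixture(scope="session")
def clean_phantom():
    """Vessel-free, noise-free phantom (flat tissue inside the mask)."""
    return generate_phantom(
        PhantomConfig(shape=(48, 48, 32), n_vessels=0, noise_sd=0.0,
                      tissue_sd=0.0, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
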