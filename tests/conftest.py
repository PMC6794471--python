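import numpy as np
import pytest

from lcpca import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """24^3, 3 contrasts, moderate noise — shared by quick integration tests."""
    spec = PhantomSpec(shape=(24, 24, 24), n_contrasts=3, noise_sigma=5.0, seed=3)
    truth, noisy, labels = generate_phantom(spec)
    return spec, truth, noisy, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
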