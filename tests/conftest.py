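import numpy as np
import pytest

from ktnc.operators import SamplingMask
from ktnc.phantom import PhantomSpec, generate_phantom, simulate_measurements
from ktnc.sampling import radial_mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """32 x 32 x 16 ground-truth phantom (F, L, S), seed 1."""
    return generate_phantom(PhantomSpec(Nx=32, Ny=32, Nt=16, seed=1))


@pytest.fixture(scope="session")
def small_meas(small_phantom):
    """Noiseless 8-ray radial measurements of the small phantom."""
    F, _, _ = small_phantom
    mask = radial_mask(32, 32, 16, n_rays=8, seed=1)
    return simulate_measurements(F, mask)


@pytest.fixture(scope="session")
def full_mask():
    return SamplingMask(np.ones((32, 32, 16), dtype=bool))
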