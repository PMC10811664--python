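import numpy as np
import pytest

from molstruct import ParticleSystem, equilateral_model, sample_direct


@pytest.fixture(scope="session")
def d3_system():
    return ParticleSystem.d3_plus()


@pytest.fixture(scope="session")
def triangle_model():
    """Equilateral D3+-like planted model: side 1.65 Bohr, sigma_nuc 0.05."""
    return equilateral_model(side=1.65, sigma_nuc=0.05, sigma_e=0.6)


@pytest.fixture(scope="session")
def triangle_samples(triangle_model):
    """A moderately sized direct sample shared across tests."""
    return sample_direct(triangle_model, 1500, seed=20260921)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
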