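import numpy as np
import pytest

from aisx.passive import CableGeometry, PassiveMembrane


@pytest.fixture(scope="session")
def mem() -> PassiveMembrane:
    """Standard passive constants (Cm 0.9 µF/cm², Rm 15 kΩ·cm², Ri 100 Ω·cm)."""
    return PassiveMembrane()


@pytest.fixture(scope="session")
def axon() -> CableGeometry:
    """A 1 µm axon with a 100 µm soma."""
    return CableGeometry(d=1.0, dS=100.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# deterministic property testing: fixed example generation, no example DB
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
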