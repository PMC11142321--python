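import numpy as np
import pytest

from dss import GeneratorSpec, LinearModel, random_stable_lti


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def stable_lti():
    """A seeded random stable discrete-time model (n=4, radius 0.9)."""
    return random_stable_lti(GeneratorSpec(n=4, spectral_radius=0.9, seed=3))


@pytest.fixture
def shift_system():
    """Chain x1 -> x2 -> x3 (subdiagonal ones): observable only from the
    end of the chain."""
    A = np.zeros((3, 3))
    A[1, 0] = 1.0
    A[2, 1] = 1.0
    C = np.array([[0.0, 0.0, 1.0]])
    return A, C
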