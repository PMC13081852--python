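import numpy as np
import pytest

from genodensity import AdditiveLandscape


@pytest.fixture
def toy():
    """Two binary positions with effects [0,1] and [0,2]: fitnesses {0,1,2,3}."""
    return AdditiveLandscape(0.0, np.array([[0.0, 1.0], [0.0, 2.0]]), ("a", "b"))


@pytest.fixture
def hamming20():
    """Hamming landscape: every mutation off the optimum costs exactly 1."""
    theta = np.zeros((20, 2))
    theta[:, 1] = -1.0
    return AdditiveLandscape(0.0, theta, ("0", "1"))


def random_landscape(rng, L=None, C=None):
    L = L or int(rng.integers(2, 7))
    C = C or int(rng.integers(2, 5))
    theta = rng.normal(0, 1, size=(L, C))
    alphabet = tuple(chr(ord("a") + i) for i in range(C))
    return AdditiveLandscape(float(rng.normal()), theta, alphabet)
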