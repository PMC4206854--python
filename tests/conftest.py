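import numpy as np
import pytest

from trichosim.core_model import SystemParams


@pytest.fixture
def rng():
    return np.random.default_rng(20140902)


def random_chain(rng, n_vertices, step=1.0, jitter=0.6):
    """A random open chain with well-separated, non-degenerate vertices."""
    directions = rng.normal(size=(n_vertices - 1, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    # bias along +x so adjacent edges never come close to anti-parallel
    directions = directions * jitter + np.array([1.0, 0.0, 0.0])
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    return np.vstack([np.zeros(3), np.cumsum(step * directions, axis=0)])


@pytest.fixture
def small_params():
    """A small but mechanically realistic system for integration tests."""
    return SystemParams(width=150e-6, depth=150e-6, height=7.5e-6,
                        lam=60e-6, n_segments=10, rho=0.005, seed=7)
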