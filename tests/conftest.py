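import numpy as np
import pytest

from crossmorph.synthetic import SpeciesSpec, generate_species


@pytest.fixture(scope="session")
def block_factor_fixture():
    """Exactly representable data: disjoint non-negative orthonormal factors
    with disjoint subject weights (block-diagonal X = W H)."""
    rng = np.random.default_rng(42)
    W = np.zeros((60, 3))
    W[:20, 0] = rng.random(20) + 0.1
    W[20:40, 1] = rng.random(20) + 0.1
    W[40:, 2] = rng.random(20) + 0.1
    W /= np.linalg.norm(W, axis=0)
    H = np.zeros((3, 30))
    H[0, :10] = rng.random(10) + 0.2
    H[1, 10:20] = rng.random(10) + 0.2
    H[2, 20:] = rng.random(10) + 0.2
    return W, H, W @ H


@pytest.fixture(scope="session")
def small_species():
    """Default-condition synthetic sample on a small grid (shared, read-only)."""
    spec = SpeciesSpec(grid_shape=(14, 10, 10), k_true=5, n_subjects=60, seed=7)
    stack, truth = generate_species(spec)
    return spec, stack, truth
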