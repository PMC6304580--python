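import numpy as np
import pytest

from dlgrmc import DTIDataset, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_similarity(rng, n):
    """A valid similarity matrix: symmetric, [0,1], unit diagonal."""
    S = rng.uniform(0, 1, (n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


@pytest.fixture
def small_dataset(rng):
    d, t = 8, 6
    M = (rng.uniform(size=(d, t)) < 0.3).astype(int)
    M[0, 0] = 1  # guarantee at least one interaction
    return DTIDataset(
        tuple(f"d{i}" for i in range(d)),
        tuple(f"t{j}" for j in range(t)),
        M,
        random_similarity(rng, d),
        random_similarity(rng, t),
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """The default-scale synthetic dataset (54 x 26, rank 3)."""
    return generate(SyntheticSpec(seed=0))
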