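import numpy as np
import pytest

from strokenet.parcellation import make_default_parcellation


@pytest.fixture(scope="session")
def parcellation():
    return make_default_parcellation()


def random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    """Symmetric non-negative weighted adjacency with zero diagonal."""
    adj = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < p
    weights = rng.uniform(0.05, 1.0, size=iu[0].size)
    adj[iu] = np.where(present, weights, 0.0)
    return adj + adj.T


@pytest.fixture
def graph_factory():
    return random_weighted_graph
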