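import numpy as np
import pytest
import scipy.sparse as sp

from biplink import BipartiteNetwork


@pytest.fixture
def k22_minus_edge() -> np.ndarray:
    """K_{2,2} with the (v1, w1) edge removed; the canonical worked example."""
    return np.array([[0.0, 1.0], [1.0, 1.0]])


@pytest.fixture
def small_net() -> BipartiteNetwork:
    rng = np.random.default_rng(7)
    A = (rng.random((10, 8)) < 0.3).astype(float)
    A[0, 0] = 1.0  # guarantee at least one edge
    return BipartiteNetwork(
        [f"v{i}" for i in range(10)], [f"w{j}" for j in range(8)], sp.csr_matrix(A)
    )


def random_adjacency(rng: np.random.Generator, max_n: int = 12, max_m: int = 12,
                     density: float | None = None) -> np.ndarray:
    """A random binary matrix with random shape; may contain isolated nodes."""
    n = int(rng.integers(2, max_n + 1))
    m = int(rng.integers(2, max_m + 1))
    d = density if density is not None else float(rng.uniform(0.1, 0.5))
    return (rng.random((n, m)) < d).astype(float)
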