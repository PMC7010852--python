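import numpy as np
import pytest

from puimc import AdjacencyMatrix, TransitionMatrix, row_normalize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng: np.random.Generator, n: int, density: float = 0.4) -> AdjacencyMatrix:
    """Random symmetric weighted graph with no isolated nodes."""
    A = rng.random((n, n)) * (rng.random((n, n)) < density)
    A = np.triu(A, 1)
    A = A + A.T
    # guarantee no zero row so Eq-style normalization is exercised directly
    for i in range(n):
        if A[i].sum() == 0:
            j = (i + 1) % n
            A[i, j] = A[j, i] = 1.0
    return AdjacencyMatrix(A, [f"v{i}" for i in range(n)])


def random_transition(rng: np.random.Generator, n: int) -> TransitionMatrix:
    return row_normalize(random_adjacency(rng, n))


def rwr_linear_solve(B: np.ndarray, p: float) -> np.ndarray:
    """Closed-form RWR stationary states: rows s_i = p·δ_i·(I − (1−p)B)⁻¹."""
    n = B.shape[0]
    return p * np.linalg.inv(np.eye(n) - (1 - p) * B)
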