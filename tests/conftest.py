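import numpy as np
import pytest

from connectopath.io import ConnectivityMatrix
from connectopath.simulate import CohortConfig, generate_cohort


def random_weight_matrix(
    rng: np.random.Generator, n: int, density: float = 0.7,
    low: float = 1.0, high: float = 10.0,
) -> np.ndarray:
    """Random symmetric non-negative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    vals = rng.uniform(low, high, len(iu[0]))
    w[iu] = np.where(present, vals, 0.0)
    return w + w.T


def floyd_warshall_reference(dist: np.ndarray) -> np.ndarray:
    """Independent triple-loop Floyd–Warshall on a distance matrix."""
    d = dist.copy()
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


@pytest.fixture
def chain_matrix() -> ConnectivityMatrix:
    # A-B count 2, B-C count 4
    return ConnectivityMatrix(
        ["A", "B", "C"], np.array([[0.0, 2, 0], [2, 0, 4], [0, 4, 0]])
    )


@pytest.fixture
def triangle_matrix() -> ConnectivityMatrix:
    # AB=10, BC=10, AC=1: detour A-B-C (0.2) beats direct A-C (1.0)
    return ConnectivityMatrix(
        ["A", "B", "C"], np.array([[0.0, 10, 1], [10, 0, 10], [1, 10, 0]])
    )


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_control=3, n_exposed=8, n_ptsd=8, n_nodes=16, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
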