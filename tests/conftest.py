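import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from covmod.cohort import Partition
from covmod.network import CorrelationNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def symmetric_weights(rng: np.random.Generator, n: int, density: float = 1.0) -> np.ndarray:
    """Random non-negative symmetric weight matrix with zero diagonal."""
    w = rng.uniform(0.0, 1.0, size=(n, n))
    if density < 1.0:
        w *= rng.uniform(size=(n, n)) < density
    w = np.triu(w, k=1)
    return w + w.T


def make_network(r: np.ndarray, n_subjects: int = 50, group: str = "g") -> CorrelationNetwork:
    """Wrap a signed correlation matrix as a CorrelationNetwork."""
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 0.0)
    labels = tuple(f"R{i + 1}" for i in range(r.shape[0]))
    return CorrelationNetwork(
        weights=r.copy(), signed_r=r, node_labels=labels, group=group, n_subjects=n_subjects
    )


@pytest.fixture
def four_node_weights() -> np.ndarray:
    """Edges a-b:1, c-d:1, a-c:1; hand-computed Q({ab|cd}) = 1/6."""
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    w[0, 2] = w[2, 0] = 1.0
    return w


@pytest.fixture
def two_cliques() -> tuple[np.ndarray, Partition]:
    """Two disconnected equal-weight 3-cliques; Q of the clique split = 0.5."""
    w = np.zeros((6, 6))
    for block in (slice(0, 3), slice(3, 6)):
        w[block, block] = 1.0
    np.fill_diagonal(w, 0.0)
    return w, Partition.from_labels([1, 1, 1, 2, 2, 2])
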