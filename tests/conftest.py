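import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from singlefile import AggregateGraph

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_weighted_graph(
    rng: np.random.Generator, n_nodes: int, density: float = 0.5, max_weight: int = 5
) -> AggregateGraph:
    """Random symmetric integer-weight graph with at least one edge."""
    while True:
        mask = rng.random((n_nodes, n_nodes)) < density
        w = rng.integers(1, max_weight + 1, size=(n_nodes, n_nodes)) * mask
        w = np.triu(w, k=1)
        w = w + w.T
        if w.sum() > 0:
            return AggregateGraph(weights=w.astype(np.int64))


def random_partition_labels(rng: np.random.Generator, n_nodes: int, k: int) -> np.ndarray:
    """Random assignment of n_nodes into exactly k non-empty clusters."""
    while True:
        labels = rng.integers(1, k + 1, size=n_nodes)
        if np.unique(labels).size == k:
            return labels


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
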