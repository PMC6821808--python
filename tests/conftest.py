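import numpy as np
import pytest

from curvnet.netio import WeightedGraph


def make_graph(weights) -> WeightedGraph:
    return WeightedGraph(weights=np.asarray(weights, dtype=float))


def complete_graph(n: int, weight: float = 1.0) -> WeightedGraph:
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(weights=w)


def path_graph(n: int) -> WeightedGraph:
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return WeightedGraph(weights=w)


def star_graph(n_leaves: int) -> WeightedGraph:
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = w[1:, 0] = 1.0
    return WeightedGraph(weights=w)


def cycle_graph(n: int) -> WeightedGraph:
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    return WeightedGraph(weights=w)


def random_weighted_graph(
    n: int, density: float, rng: np.random.Generator, integer_weights: bool = False
) -> WeightedGraph:
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < density
    if integer_weights:
        # powers of two keep 1/w and sums of 1/w exact in floating point,
        # so co-optimal shortest paths are detected identically by any solver
        vals = rng.choice([1.0, 2.0, 4.0], int(mask.sum()))
    else:
        vals = rng.exponential(1.0, int(mask.sum()))
    tri = np.zeros(iu[0].size)
    tri[mask] = vals
    w[iu] = tri
    return WeightedGraph(weights=w + w.T)


@pytest.fixture
def k3():
    return complete_graph(3)


@pytest.fixture
def k4():
    return complete_graph(4)


@pytest.fixture
def path3():
    return path_graph(3)


@pytest.fixture
def star4():
    """Hub with 3 leaves (K_{1,3})."""
    return star_graph(3)


@pytest.fixture
def single_edge():
    return make_graph([[0, 1], [1, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
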