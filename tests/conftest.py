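import numpy as np
import pytest

from msconnectome.connectome import BrainGraph, ConnectivityMatrix
from msconnectome.synthetic_data import CohortConfig, GroupSpec


def random_weighted_graph(rng: np.random.Generator, n: int | None = None,
                          p: float = 0.5) -> BrainGraph:
    """Small random graph with dyadic integer weights (exact path arithmetic)."""
    if n is None:
        n = int(rng.integers(3, 9))
    values = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < p
    weights = rng.choice([1, 2, 4, 8], size=iu[0].size)
    values[iu] = np.where(present, weights, 0)
    values += values.T
    return BrainGraph(values, weighted=True, tau=1.0,
                      n_edges_kept=int(present.sum()))


def graph_from_array(values) -> BrainGraph:
    values = np.asarray(values, dtype=float)
    n_edges = int(np.count_nonzero(np.triu(values, k=1)))
    return BrainGraph(values, weighted=True, tau=1.0, n_edges_kept=n_edges)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def triangle_graph() -> BrainGraph:
    """K3 with unit weights."""
    return graph_from_array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


@pytest.fixture
def path3_graph() -> BrainGraph:
    """P3: 0 - 1 - 2."""
    return graph_from_array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture
def star4_graph() -> BrainGraph:
    """Star with center 0 and three leaves."""
    values = np.zeros((4, 4))
    values[0, 1:] = 1
    values[1:, 0] = 1
    return graph_from_array(values)


@pytest.fixture
def tiny_cohort_config() -> CohortConfig:
    """Small two-group cohort for fast pipeline tests."""
    return CohortConfig(
        n_nodes=30,
        groups=(GroupSpec("HC", 6, 2, 0.0), GroupSpec("SP", 6, 2, 0.7)),
        seed=7,
    )
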