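import networkx as nx
import numpy as np
import pytest

from tecnet.matrices import CovariationMatrix


def random_weighted_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph with Uniform(0.5, 1) weights (labels 'n0'...)."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}", weight=float(rng.uniform(0.5, 1.0)))
    return g


def random_covariation(n: int, seed: int) -> CovariationMatrix:
    """Symmetric scores drawn uniformly from [-1, 1], unit diagonal."""
    rng = np.random.default_rng(seed)
    s = rng.uniform(-1.0, 1.0, size=(n, n))
    s = np.triu(s, 1)
    s = s + s.T
    np.fill_diagonal(s, 1.0)
    return CovariationMatrix([f"g{i:03d}" for i in range(n)], s)


@pytest.fixture
def small_weighted_graph() -> nx.Graph:
    return random_weighted_graph(20, 0.25, seed=42)


@pytest.fixture
def small_cov() -> CovariationMatrix:
    return random_covariation(15, seed=7)
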