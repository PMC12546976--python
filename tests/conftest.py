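import networkx as nx
import numpy as np
import pytest

from biorank import FixtureConfig, PPINetwork, generate_fixture


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size fixture configuration for fast unit tests."""
    return FixtureConfig(seed=42, n_genes=120, n_edges=420, module_size=15,
                         n_seeds=5, n_tumor=20, n_control=10,
                         n_terms=25, n_disease_terms=4)


@pytest.fixture(scope="session")
def bundle(small_cfg):
    return generate_fixture(small_cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """One bundle at the full default (study-condition) scale."""
    return generate_fixture(FixtureConfig(seed=7))


def random_network(rng: np.random.Generator, n_nodes: int,
                   extra_edges: int) -> PPINetwork:
    """Random connected graph: spanning tree plus ``extra_edges`` extras."""
    names = [f"N{i:03d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    perm = list(rng.permutation(names))
    for i in range(1, n_nodes):
        g.add_edge(perm[i], perm[int(rng.integers(0, i))], confidence=0.9)
    max_extra = n_nodes * (n_nodes - 1) // 2 - g.number_of_edges()
    extra_edges = min(extra_edges, max_extra)
    placed = 0
    while placed < extra_edges:
        u, v = rng.choice(names, size=2, replace=False)
        if not g.has_edge(u, v):
            g.add_edge(u, v, confidence=0.9)
            placed += 1
    return PPINetwork(g)
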