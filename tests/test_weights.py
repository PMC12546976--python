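"""Seed-proximity phi, personalization q, and the edge kernels W1/W2/W."""

import networkx as nx
import numpy as np
import pytest

from biorank import (AnnotationCatalog, build_personalization,
                     combine_edge_weights, compute_phi, compute_w1,
                     compute_w2, dsi)
from biorank.io import PPINetwork

from conftest import random_network


def path_network(*names):
    g = nx.Graph()
    for a, b in zip(names, names[1:]):
        g.add_edge(a, b, confidence=0.9)
    return PPINetwork(g)


def bfs_phi_oracle(network, seeds, de_genes):
    """Independent oracle: breadth-first distances, then the two ratios."""
    out = {}
    for gene in network.nodes:
        if gene not in de_genes:
            out[gene] = 0.0
            continue
        dist = nx.single_source_shortest_path_length(network.graph, gene, cutoff=2)
        first = {g for g, d in dist.items() if d == 1}
        second = {g for g, d in dist.items() if d == 2}
        val = 0.0
        if first:
            val += len(first & seeds) / len(first)
        if second:
            val += len(second & seeds) / len(second)
        out[gene] = val
    return out


class TestComputePhi:
    def test_four_node_path(self):
        """a-b-c-d with seeds {a}, DE {c}: N(c)={b,d}, N2(c)={a} -> phi_c=1."""
        net = path_network("a", "b", "c", "d")
        phi = compute_phi(net, {"a"}, {"c"})
        assert phi["c"] == pytest.approx(1.0)
        assert phi["a"] == phi["b"] == phi["d"] == 0.0

    def test_all_seed_neighborhood_gives_two(self):
        g = nx.Graph()
        g.add_edge("x", "s1", confidence=0.9)
        g.add_edge("s1", "s2", confidence=0.9)
        net = PPINetwork(g)
        phi = compute_phi(net, {"s1", "s2"}, {"x"})
        assert phi["x"] == pytest.approx(2.0)

    def test_non_de_gene_is_zero(self):
        net = path_network("a", "b", "c")
        phi = compute_phi(net, {"a"}, set())
        assert all(v == 0.0 for v in phi.values())

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(5, 50))
            net = random_network(rng, n, int(rng.integers(0, 2 * n)))
            seeds = set(rng.choice(net.nodes, size=max(1, n // 5), replace=False))
            de = set(rng.choice(net.nodes, size=max(1, n // 3), replace=False))
            assert compute_phi(net, seeds, de) == pytest.approx(
                bfs_phi_oracle(net, seeds, de))

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(22)
        net = random_network(rng, 20, 25)
        seeds = set(net.nodes[:4])
        de = set(net.nodes[5:12])
        relabel = {g: f"Z{i:02d}" for i, g in enumerate(reversed(net.nodes))}
        net2 = PPINetwork(nx.relabel_nodes(net.graph, relabel))
        phi1 = compute_phi(net, seeds, de)
        phi2 = compute_phi(net2, {relabel[s] for s in seeds},
                           {relabel[d] for d in de})
        for g in net.nodes:
            assert phi2[relabel[g]] == pytest.approx(phi1[g])


class TestPersonalization:
    NODES = ("a", "b", "c", "d")
    THETA = {"a": 8.0, "b": 2.0, "c": 0.0, "d": 0.0}
    PHI = {"a": 0.0, "b": 1.0, "c": 1.0, "d": 0.0}

    def test_alpha_endpoints(self):
        q1 = build_personalization(self.THETA, self.PHI, 1.0, self.NODES).q
        assert q1 == pytest.approx([0.8, 0.2, 0.0, 0.0])
        q0 = build_personalization(self.THETA, self.PHI, 0.0, self.NODES).q
        assert q0 == pytest.approx([0.0, 0.5, 0.5, 0.0])

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.9])
    def test_convexity(self, alpha):
        nb = build_personalization(self.THETA, self.PHI, alpha, self.NODES)
        assert nb.q.sum() == pytest.approx(1.0, abs=1e-12)
        assert nb.q.min() >= 0.0

    def test_zero_phi_falls_back_to_uniform(self):
        phi = {g: 0.0 for g in self.NODES}
        nb = build_personalization(self.THETA, phi, 0.5, self.NODES)
        assert nb.q == pytest.approx(
            0.5 * np.array([0.8, 0.2, 0, 0]) + 0.5 / 4)

    def test_zero_theta_errors(self):
        theta = {g: 0.0 for g in self.NODES}
        with pytest.raises(ValueError, match="theta"):
            build_personalization(theta, self.PHI, 0.5, self.NODES)


def catalog_for(annotations: dict[str, set]):
    """Build a single-source catalog realizing the given A(i) term sets."""
    terms: dict[str, set] = {}
    for gene, names in annotations.items():
        for t in names:
            terms.setdefault(t, set()).add(gene)
    return AnnotationCatalog({"src": {t: frozenset(g) for t, g in terms.items()}})


class TestEdgeKernels:
    def test_dsi_set_arithmetic(self):
        cat = catalog_for({"i": {"t1", "t2"}, "j": {"t2", "t3"}})
        F_all = frozenset({("src", "t2"), ("src", "t3")})
        assert dsi("i", "j", cat, F_all) == 1
        assert dsi("i", "j", cat, frozenset()) == 0
        cat2 = catalog_for({"i": {"t1", "t2", "t3"}, "j": {"t1", "t2", "t3"}})
        F3 = frozenset({("src", t) for t in ("t1", "t2", "t3")})
        assert dsi("i", "j", cat2, F3) == 3

    def test_w1_floor_and_shared_terms(self):
        net = path_network("i", "j", "k")
        cat = catalog_for({"i": {"t1", "t2", "t3"}, "j": {"t1", "t2", "t3"}})
        F = frozenset({("src", t) for t in ("t1", "t2", "t3")})
        w1 = compute_w1(net, cat, F, c=0.1)
        idx = net.node_index
        assert w1[idx["i"], idx["j"]] == pytest.approx(3.1)
        assert w1[idx["j"], idx["k"]] == pytest.approx(0.1)   # floor
        assert w1[idx["i"], idx["k"]] == 0.0                  # non-adjacent
        assert (abs(w1 - w1.T) > 1e-15).nnz == 0              # symmetric

    def test_w2_row_normalization(self):
        net = path_network("u", "i", "v")   # i has neighbors u, v
        corr = {frozenset(("i", "u")): 0.6, frozenset(("i", "v")): 0.2}
        w2 = compute_w2(corr, net)
        idx = net.node_index
        assert w2[idx["i"], idx["u"]] == pytest.approx(0.75)
        assert w2[idx["i"], idx["v"]] == pytest.approx(0.25)
        assert w2[idx["u"], idx["i"]] == pytest.approx(1.0)   # single neighbor

    def test_w2_negative_rows_fall_back_to_uniform(self):
        net = path_network("u", "i", "v")
        corr = {frozenset(("i", "u")): -0.9, frozenset(("i", "v")): -0.4}
        w2 = compute_w2(corr, net)
        idx = net.node_index
        assert w2[idx["i"], idx["u"]] == pytest.approx(0.5)
        assert w2[idx["i"], idx["v"]] == pytest.approx(0.5)
        # abs mode uses magnitudes instead
        w2_abs = compute_w2(corr, net, negative="abs")
        assert w2_abs[idx["i"], idx["u"]] == pytest.approx(0.9 / 1.3)

    @pytest.mark.parametrize("beta", [0.0, 0.3, 1.0])
    def test_combined_rows_are_stochastic(self, beta):
        rng = np.random.default_rng(31)
        net = random_network(rng, 25, 40)
        cat = catalog_for({g: {f"t{rng.integers(0, 5)}"} for g in net.nodes})
        F = frozenset({("src", f"t{i}") for i in range(5)})
        corr = {frozenset((u, v)): float(rng.uniform(-1, 1))
                for u, v, _ in net.edges()}
        w1 = compute_w1(net, cat, F, c=0.1)
        w2 = compute_w2(corr, net)
        bundle = combine_edge_weights(w1, w2, beta, net.nodes)
        rows = np.asarray(bundle.w.sum(axis=1)).ravel()
        assert rows == pytest.approx(np.ones(net.n_nodes), abs=1e-12)
        # the c-floor keeps every directed PPI arc in the support once W1
        # participates; pure W2 may zero clipped arcs but never adds new ones
        directed = {(net.node_index[u], net.node_index[v])
                    for u, v, _ in net.edges()}
        directed |= {(j, i) for i, j in directed}
        coo = bundle.w.tocoo()
        support = set(zip(coo.row.tolist(), coo.col.tolist()))
        if beta > 0:
            assert support == directed
        else:
            assert support <= directed
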