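"""Edge kernels and score propagation on a five-gene toy network.

Shows how shared significant annotations (W1, floored at c) and clipped
co-expression (W2) mix into one row-stochastic kernel, and how personalized
PageRank concentrates mass near the seeded side of the graph.
"""

import networkx as nx
import numpy as np

from biorank import (AnnotationCatalog, build_personalization,
                     combine_edge_weights, compute_w1, compute_w2,
                     personalized_pagerank)
from biorank.io import PPINetwork
from biorank.pagerank import PageRankConfig, rank_genes

g = nx.Graph()
for a, b in [("s", "a"), ("a", "b"), ("b", "c"), ("c", "d"), ("s", "b")]:
    g.add_edge(a, b, confidence=0.9)
net = PPINetwork(g)

catalog = AnnotationCatalog({"demo": {
    "pathway": frozenset({"s", "a", "b"}),   # the seeded trio shares a term
}})
F = frozenset({("demo", "pathway")})

corr = {frozenset(("s", "a")): 0.9, frozenset(("a", "b")): 0.8,
        frozenset(("b", "c")): 0.1, frozenset(("c", "d")): -0.5,
        frozenset(("s", "b")): 0.7}

w1 = compute_w1(net, catalog, F, c=0.1)
w2 = compute_w2(corr, net)
bundle = combine_edge_weights(w1, w2, beta=0.5, nodes=net.nodes)

idx = net.node_index
print("edge (a,b): W1 = c + shared terms =", w1[idx["a"], idx["b"]])
print("edge (c,d): W1 floor only =", round(w1[idx["c"], idx["d"]], 3))
print("row sums of the mixed kernel:",
      np.round(np.asarray(bundle.w.sum(axis=1)).ravel(), 12))

theta = {n: (1000.0 if n == "s" else 0.0) for n in net.nodes}
phi = {n: 0.0 for n in net.nodes}
node_bundle = build_personalization(theta, phi, alpha=1.0,
                                    node_order=net.nodes)
scores = personalized_pagerank(bundle, node_bundle.q, PageRankConfig())
ranking = rank_genes(scores)
print("\npropagated scores (teleport to the seed 's'):")
for rank, gene, score in ranking.entries:
    print(f"  {rank}  {gene}  {score:.4f}")
print("Genes sharing the seed's pathway and strong co-expression ('a', 'b')"
      "\noutrank the weakly connected periphery ('c', 'd').")
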