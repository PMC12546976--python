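"""Node personalization and edge transition weights.

The personalization vector q mixes two normalized node scores: the
annotation score theta (seeds carry a large constant, other genes their
overlap with significantly enriched terms) and the seed-proximity score phi,
which for each differentially expressed gene is the fraction of its first-
and second-order neighborhoods occupied by seeds.

Edge weights mix two row-stochastic kernels over the directed edge set
induced by the undirected PPI graph: W1 from the count of significant
annotations shared by an edge's endpoints (with a positive floor c so no
edge silently vanishes), and W2 from non-negative Pearson co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .enrichment import ThetaVector
from .expression import DEGeneSet
from .io import AnnotationCatalog, PPINetwork, logger

__all__ = [
    "NodeWeightBundle",
    "EdgeWeightBundle",
    "compute_phi",
    "build_personalization",
    "dsi",
    "compute_w1",
    "compute_w2",
    "combine_edge_weights",
]


def compute_phi(network: PPINetwork,
                seeds: Iterable[str],
                de: DEGeneSet | Iterable[str]) -> dict[str, float]:
    """Seed-proximity score for differentially expressed genes.

    phi_i = |N(i) ∩ S| / |N(i)| + |N2(i) ∩ S| / |N2(i)| for DE genes, with a
    term contributing 0 when its neighborhood is empty; phi_i = 0 for
    non-DE genes.  Values lie in [0, 2].
    """
    seed_set = set(seeds)
    de_genes = de.genes if isinstance(de, DEGeneSet) else set(de)
    phi: dict[str, float] = {}
    for gene in network.nodes:
        if gene not in de_genes:
            phi[gene] = 0.0
            continue
        first = network.neighbors(gene)
        second = network.second_neighbors(gene)
        value = 0.0
        if first:
            value += len(first & seed_set) / len(first)
        if second:
            value += len(second & seed_set) / len(second)
        phi[gene] = value
    return phi


@dataclass
class NodeWeightBundle:
    """theta, phi and their convex mix q over a fixed node order."""

    nodes: tuple[str, ...]
    theta: np.ndarray
    phi: np.ndarray
    alpha: float
    q: np.ndarray

    def q_of(self, gene: str) -> float:
        return float(self.q[self.nodes.index(gene)])


def build_personalization(theta: ThetaVector | Mapping[str, float],
                          phi: Mapping[str, float],
                          alpha: float,
                          node_order: Sequence[str]) -> NodeWeightBundle:
    """q = alpha * theta_hat + (1 - alpha) * phi_hat, each hat-vector
    normalized to sum 1.

    An all-zero phi (no DE genes, or none near seeds) is replaced by the
    uniform vector so q remains a proper distribution; an all-zero theta is
    an error because it means no seed was scored.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    theta_map = theta.values if isinstance(theta, ThetaVector) else theta
    t = np.array([theta_map[g] for g in node_order], dtype=float)
    f = np.array([phi[g] for g in node_order], dtype=float)
    if np.any(t < 0) or np.any(f < 0):
        raise ValueError("theta and phi must be non-negative")
    ts = t.sum()
    if ts == 0:
        raise ValueError("theta is identically zero: no seed gene was scored")
    t_hat = t / ts
    fs = f.sum()
    if fs == 0:
        logger.info("phi is identically zero; falling back to the uniform vector")
        f_hat = np.full(len(node_order), 1.0 / len(node_order))
    else:
        f_hat = f / fs
    q = alpha * t_hat + (1.0 - alpha) * f_hat
    q /= q.sum()  # guard against rounding drift
    return NodeWeightBundle(tuple(node_order), t, f, alpha, q)


def dsi(i: str, j: str,
        catalog: AnnotationCatalog,
        F: frozenset[tuple[str, str]]) -> int:
    """Disease-specific similarity: number of significant (source, term)
    annotations shared by genes ``i`` and ``j``."""
    if i == j:
        raise ValueError("DSI is defined for distinct genes")
    return len(catalog.annotations(i) & catalog.annotations(j) & F)


def _row_normalize(mat: sp.csr_matrix) -> sp.csr_matrix:
    """Scale each non-empty row to sum 1; empty rows stay empty (dangling)."""
    sums = np.asarray(mat.sum(axis=1)).ravel()
    scale = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sp.diags(scale) @ mat


def compute_w1(network: PPINetwork,
               catalog: AnnotationCatalog,
               F: frozenset[tuple[str, str]],
               c: float = 0.1) -> sp.csr_matrix:
    """Annotation edge kernel: W1[i, j] = c + DSI(i, j) on every directed
    arc induced by the PPI graph, 0 elsewhere; symmetric before
    normalization."""
    if c <= 0:
        raise ValueError(f"edge-weight floor c must be positive, got {c}")
    idx = network.node_index
    rows, cols, vals = [], [], []
    # restrict each gene's annotation set to F once
    sig_ann = {g: (catalog.annotations(g) & F) for g in network.nodes}
    for u, v, _ in network.edges():
        w = c + len(sig_ann[u] & sig_ann[v])
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        vals += [w, w]
    n = network.n_nodes
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def compute_w2(correlations: Mapping[frozenset[str], float],
               network: PPINetwork,
               negative: str = "clip") -> sp.csr_matrix:
    """Co-expression edge kernel: per-row normalized non-negative Pearson
    correlations over each gene's PPI neighbors.

    ``negative`` chooses how anti-correlation is handled: "clip" zeroes
    negative values (a row whose clipped sum is 0 falls back to the uniform
    distribution over its neighbors); "abs" uses absolute values.
    """
    if negative not in ("clip", "abs"):
        raise ValueError(f"negative-correlation mode must be clip|abs, got {negative!r}")
    idx = network.node_index
    n = network.n_nodes
    rows, cols, vals = [], [], []
    for gene in network.nodes:
        nbrs = sorted(network.neighbors(gene))
        if not nbrs:
            continue  # dangling row
        raw = np.array([correlations.get(frozenset((gene, v)), 0.0) for v in nbrs])
        pos = np.abs(raw) if negative == "abs" else np.clip(raw, 0.0, None)
        total = pos.sum()
        if total == 0:
            weights = np.full(len(nbrs), 1.0 / len(nbrs))
        else:
            weights = pos / total
        i = idx[gene]
        for v, w in zip(nbrs, weights):
            if w > 0:
                rows.append(i)
                cols.append(idx[v])
                vals.append(w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


@dataclass
class EdgeWeightBundle:
    """Row-stochastic annotation and co-expression kernels and their mix."""

    nodes: tuple[str, ...]
    w1: sp.csr_matrix       # raw c + DSI weights (symmetric)
    w2: sp.csr_matrix       # row-normalized co-expression
    beta: float
    w: sp.csr_matrix        # beta * row_norm(w1) + (1 - beta) * w2


def combine_edge_weights(w1: sp.csr_matrix,
                         w2: sp.csr_matrix,
                         beta: float,
                         nodes: Sequence[str]) -> EdgeWeightBundle:
    """Convex mix of the two kernels after row-normalizing W1.

    W1 entries sit on an additive scale (>= c) while W2 rows already sum to
    1, so W1 is normalized first; beta then balances two row-stochastic
    kernels and every non-dangling row of the result sums to 1.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    w1_hat = _row_normalize(w1.tocsr())
    w = (beta * w1_hat + (1.0 - beta) * w2.tocsr()).tocsr()
    return EdgeWeightBundle(tuple(nodes), w1.tocsr(), w2.tocsr(), beta, w)
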