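"""Personalized PageRank propagation and the classic uniform baseline.

The score vector is the fixed point of

    PR(v) = (1 - d) * q(v) + d * sum_{u in B(v)} PR(u) * w(u, v) / sum_k w(u, k)

found by power iteration on the row-stochastic transition kernel W, with the
teleport distribution q.  Mass sitting on dangling rows (nodes with no
outgoing weight) is redistributed through q so the scores stay a probability
distribution at every iteration.  The classic baseline is the same iteration
with uniform q and uniform out-weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .io import PPINetwork, RankingResult
from .weights import EdgeWeightBundle, _row_normalize

__all__ = [
    "PageRankConfig",
    "ScoreVector",
    "ConvergenceError",
    "personalized_pagerank",
    "classic_pagerank",
    "rank_genes",
]


@dataclass(frozen=True)
class PageRankConfig:
    damping: float = 0.85
    tol: float = 1e-10          # L1 change between iterations
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.damping < 1.0:
            raise ValueError(f"damping must be in [0, 1), got {self.damping}")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance; carries the residual."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"PageRank did not converge in {iterations} iterations "
            f"(final L1 residual {residual:.3e})"
        )


@dataclass
class ScoreVector:
    """Converged PageRank scores over a fixed node order."""

    nodes: tuple[str, ...]
    scores: np.ndarray
    iterations: int
    residual: float

    def as_dict(self) -> dict[str, float]:
        return {g: float(s) for g, s in zip(self.nodes, self.scores)}


def _power_iteration(w: sp.csr_matrix,
                     q: np.ndarray,
                     cfg: PageRankConfig,
                     nodes: Sequence[str]) -> ScoreVector:
    n = len(q)
    if w.shape != (n, n):
        raise ValueError("transition matrix and personalization disagree in size")
    if abs(q.sum() - 1.0) > 1e-9 or np.any(q < 0):
        raise ValueError("personalization must be a probability distribution")
    d = cfg.damping
    row_sums = np.asarray(w.sum(axis=1)).ravel()
    dangling = row_sums <= 1e-15
    wt = w.T.tocsr()
    x = q.copy()
    for it in range(1, cfg.max_iter + 1):
        dangling_mass = x[dangling].sum() if dangling.any() else 0.0
        x_new = (1.0 - d) * q + d * (wt @ x + dangling_mass * q)
        total = x_new.sum()
        assert abs(total - 1.0) < 1e-9, "probability mass not conserved"
        x_new /= total
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < cfg.tol:
            return ScoreVector(tuple(nodes), x, it, residual)
    raise ConvergenceError(residual, cfg.max_iter)


def personalized_pagerank(weights: EdgeWeightBundle | sp.csr_matrix,
                          q: np.ndarray,
                          cfg: PageRankConfig = PageRankConfig(),
                          nodes: Sequence[str] | None = None) -> ScoreVector:
    """Propagate the personalization q over the weighted kernel.

    ``weights`` is either an :class:`EdgeWeightBundle` (whose mixed kernel W
    and node order are used) or a raw row-stochastic sparse matrix, in which
    case ``nodes`` must name the rows.
    """
    if isinstance(weights, EdgeWeightBundle):
        w, node_order = weights.w, weights.nodes
    else:
        if nodes is None:
            raise ValueError("nodes must be given with a raw matrix")
        w, node_order = weights, tuple(nodes)
    return _power_iteration(w, np.asarray(q, dtype=float), cfg, node_order)


def classic_pagerank(network: PPINetwork,
                     cfg: PageRankConfig = PageRankConfig()) -> ScoreVector:
    """Classic PageRank on the unweighted PPI graph: uniform teleport 1/N
    and uniform out-weights 1/L(u)."""
    n = network.n_nodes
    if n == 0:
        raise ValueError("empty network")
    idx = network.node_index
    rows, cols = [], []
    for u, v, _ in network.edges():
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    w = _row_normalize(adj)
    q = np.full(n, 1.0 / n)
    return _power_iteration(w, q, cfg, network.nodes)


def rank_genes(scores: ScoreVector,
               seeds: Iterable[str] = (),
               include_seeds: bool = True,
               meta: dict | None = None) -> RankingResult:
    """Deterministic ranking: descending score, ties broken by ascending
    gene identifier; optionally drop seed genes before assigning ranks."""
    values = scores.as_dict()
    if not all(np.isfinite(v) for v in values.values()):
        raise ValueError("scores must be finite")
    seed_set = set(seeds)
    items = [(g, s) for g, s in values.items()
             if include_seeds or g not in seed_set]
    items.sort(key=lambda gs: (-gs[1], gs[0]))
    entries = [(rank, g, s) for rank, (g, s) in enumerate(items, start=1)]
    meta = dict(meta or {})
    meta.setdefault("iterations", scores.iterations)
    meta.setdefault("residual", scores.residual)
    meta.setdefault("include_seeds", include_seeds)
    return RankingResult(entries, meta)
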