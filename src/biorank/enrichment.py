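"""Seed-set annotation enrichment and the annotation-based node score.

For each annotation term a one-sided Fisher exact test asks whether the term
is over-represented among the seed genes relative to the network-gene
universe.  P-values are corrected per source with the Benjamini-Hochberg
step-up procedure and terms with an adjusted value strictly below the
significance level form the reliable sets F_j (per source) and their union F.

The node score theta rewards genes whose annotations overlap F: a seed gene
receives a large constant ``ell`` so known disease genes always carry the
highest possible prior mass, while a non-seed gene i receives

    theta_i = sum_j |A(i) ∩ F_j| / |F_j|

over sources j with non-empty F_j, where A(i) is the set of (source, term)
annotations of gene i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io import AnnotationCatalog, logger

__all__ = [
    "fisher_one_sided",
    "bh_adjust",
    "select_significant_terms",
    "compute_theta",
    "SignificantTermSets",
    "TermRecord",
    "ThetaVector",
]


def fisher_one_sided(k, K, n, N):
    """One-sided (over-representation) Fisher exact p-value.

    P(X >= k) for X ~ Hypergeometric(N, n, K): drawing K seeds from a
    universe of N genes of which n carry the term, and observing k carriers
    among the seeds.  Accepts scalars or broadcastable arrays; returns a
    float for scalar input.
    """
    k = np.asarray(k)
    K = np.asarray(K)
    n = np.asarray(n)
    N = np.asarray(N)
    if np.any(k < 0) or np.any(K < 0) or np.any(n < 0) or np.any(N < 0):
        raise ValueError("contingency counts must be non-negative")
    if np.any(k > n) or np.any(k > K):
        raise ValueError("inconsistent counts: k cannot exceed n or K")
    if np.any(K > N) or np.any(n > N):
        raise ValueError("inconsistent counts: K and n cannot exceed N")
    p = hypergeom.sf(k - 1, N, n, K)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped
    at 1; an empty input yields an empty array.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


@dataclass(frozen=True)
class TermRecord:
    """Book-keeping for one enrichment test (one term against the seeds)."""

    source: str
    term: str
    k: int          # |term ∩ seeds|
    K: int          # |seeds ∩ universe|
    n: int          # |term ∩ universe|
    N: int          # |universe|
    p: float
    adjusted: float
    retained: bool


@dataclass
class SignificantTermSets:
    """Reliable annotation sets F_j per source and their union F."""

    per_source: dict[str, frozenset[tuple[str, str]]]
    records: list[TermRecord]
    level: float

    @property
    def union(self) -> frozenset[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for terms in self.per_source.values():
            out |= terms
        return frozenset(out)


def select_significant_terms(catalog: AnnotationCatalog,
                             seeds: Iterable[str],
                             universe: Iterable[str],
                             level: float = 1e-5,
                             pooled: bool = False) -> SignificantTermSets:
    """Fisher-test every term for over-representation in the seed set and
    retain those whose BH-adjusted value is strictly below ``level``.

    Adjustment is applied per source by default (each source is its own term
    family); ``pooled=True`` corrects across all sources jointly.
    """
    universe = set(universe)
    seed_set = set(seeds) & universe
    if not seed_set:
        raise ValueError("no seed genes present in the universe")
    N, K = len(universe), len(seed_set)

    raw: dict[str, list[tuple[str, int, int]]] = {}  # source -> (term, k, n)
    for source in catalog.sources:
        raw[source] = []
        for term, genes in catalog.terms[source].items():
            inside = genes & universe
            if not inside:
                continue
            n = len(inside)
            k = len(inside & seed_set)
            raw[source].append((term, k, n))

    def pvals(items: list[tuple[str, int, int]]) -> np.ndarray:
        if not items:
            return np.empty(0)
        ks = np.array([k for _, k, _ in items])
        ns = np.array([n for _, _, n in items])
        return np.atleast_1d(fisher_one_sided(ks, K, ns, N))

    records: list[TermRecord] = []
    per_source: dict[str, frozenset[tuple[str, str]]] = {}
    if pooled:
        flat = [(s, t, k, n) for s in catalog.sources for t, k, n in raw[s]]
        p = pvals([(t, k, n) for _, t, k, n in flat])
        adj = bh_adjust(p)
        kept: dict[str, set[tuple[str, str]]] = {s: set() for s in catalog.sources}
        for (s, t, k, n), pv, av in zip(flat, p, adj):
            keep = bool(av < level)
            records.append(TermRecord(s, t, k, K, n, N, float(pv), float(av), keep))
            if keep:
                kept[s].add((s, t))
        per_source = {s: frozenset(v) for s, v in kept.items()}
    else:
        for source in catalog.sources:
            items = raw[source]
            p = pvals(items)
            adj = bh_adjust(p)
            kept_here: set[tuple[str, str]] = set()
            for (t, k, n), pv, av in zip(items, p, adj):
                keep = bool(av < level)
                records.append(
                    TermRecord(source, t, k, K, n, N, float(pv), float(av), keep))
                if keep:
                    kept_here.add((source, t))
            per_source[source] = frozenset(kept_here)

    sig = SignificantTermSets(per_source, records, level)
    logger.info(
        "enrichment: %d/%d terms retained at adjusted < %g",
        len(sig.union), len(records), level,
    )
    return sig


@dataclass
class ThetaVector:
    """Annotation-based node scores with the seed constant ``ell``."""

    values: dict[str, float]
    ell: float

    def as_array(self, node_order: Sequence[str]) -> np.ndarray:
        return np.array([self.values[g] for g in node_order])


def compute_theta(catalog: AnnotationCatalog,
                  sig: SignificantTermSets,
                  seeds: Iterable[str],
                  universe: Iterable[str],
                  ell: float = 1000.0) -> ThetaVector:
    """Annotation score per gene: ``ell`` for seeds, otherwise the summed
    per-source overlap fractions with the reliable sets F_j.

    ``ell`` must strictly exceed the number of sources — the largest value a
    non-seed can reach — so that seeds always dominate the initialization.
    """
    l = catalog.n_sources
    if ell <= l:
        raise ValueError(
            f"ell must exceed the number of sources ({l}) so seeds keep the "
            f"highest priority; got {ell}"
        )
    seed_set = set(seeds)
    values: dict[str, float] = {}
    f_sizes = {s: len(terms) for s, terms in sig.per_source.items()}
    for gene in universe:
        if gene in seed_set:
            values[gene] = ell
            continue
        a = catalog.annotations(gene)
        score = 0.0
        for source, fj in sig.per_source.items():
            if not fj:
                continue
            score += len(a & fj) / f_sizes[source]
        values[gene] = score
    return ThetaVector(values, ell)
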