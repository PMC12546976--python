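"""Ranking evaluation against a ground-truth gene set.

Binary-relevance metrics over the top K ranks: match count, Recall@K
(denominator = the full truth list as given, not its network-restricted
subset, unless ``restrict_truth`` is set), nDCG@K with the standard
1/log2(p + 1) discount, and the validation rate 100 * match / K truncated to
one decimal place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import RankingResult, logger

__all__ = [
    "EvaluationReport",
    "recall_at_k",
    "ndcg_at_k",
    "validation_rate",
    "evaluate_ranking",
    "overlap_report",
]


def _top(ranking: RankingResult | Iterable[str], k: int) -> list[str]:
    if isinstance(ranking, RankingResult):
        return ranking.top(k)
    return list(ranking)[:k]


def _truth(ranking, truth: Iterable[str], restrict: bool) -> set[str]:
    truth = set(truth)
    if restrict and isinstance(ranking, RankingResult):
        universe = set(ranking.genes)
        kept = truth & universe
        if len(kept) != len(truth):
            logger.info("evaluation: %d/%d truth genes inside the ranked universe",
                        len(kept), len(truth))
        truth = kept
    if not truth:
        raise ValueError("ground-truth set is empty")
    return truth


def recall_at_k(ranking, truth: Iterable[str], k: int,
                restrict_truth: bool = False) -> float:
    """|top-k ∩ R| / |R|."""
    if k < 1:
        raise ValueError("k must be >= 1")
    R = _truth(ranking, truth, restrict_truth)
    return len(set(_top(ranking, k)) & R) / len(R)


def ndcg_at_k(ranking, truth: Iterable[str], k: int,
              restrict_truth: bool = False) -> float:
    """Normalized discounted cumulative gain with binary relevance:
    DCG@k = sum_p rel(p) / log2(p + 1), normalized by the ideal prefix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    R = _truth(ranking, truth, restrict_truth)
    top = _top(ranking, k)
    dcg = sum(1.0 / math.log2(p + 1) for p, g in enumerate(top, start=1) if g in R)
    idcg = sum(1.0 / math.log2(p + 1) for p in range(1, min(k, len(R)) + 1))
    return dcg / idcg


def validation_rate(ranking, truth: Iterable[str], k: int) -> float:
    """100 * |top-k ∩ R| / k, truncated (not rounded) to one decimal."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = len(set(_top(ranking, k)) & set(truth))
    rate = 100.0 * hits / k
    return math.floor(rate * 10 + 1e-9) / 10


@dataclass
class EvaluationReport:
    """Top-K scorecard for one ranking against one truth set."""

    k: int
    match: int
    recall: float
    ndcg: float
    rate: float          # validation rate, percent, one decimal (truncated)
    truth_size: int

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "match": self.match,
            "recall_at_k": self.recall,
            "ndcg_at_k": self.ndcg,
            "validation_rate": self.rate,
            "truth_size": self.truth_size,
        }


def evaluate_ranking(ranking, truth: Iterable[str], k: int,
                     restrict_truth: bool = False) -> EvaluationReport:
    R = _truth(ranking, truth, restrict_truth)
    match = len(set(_top(ranking, k)) & R)
    return EvaluationReport(
        k=k,
        match=match,
        recall=recall_at_k(ranking, R, k),
        ndcg=ndcg_at_k(ranking, R, k),
        rate=validation_rate(ranking, R, k),
        truth_size=len(R),
    )


def overlap_report(rankings: Mapping[str, RankingResult], k: int) -> dict:
    """Shared and unique genes among the top-k sets of several rankings.

    All rankings must cover the same gene universe.  Returns per-method
    top-k and unique-gene counts plus the intersection size of every
    combination of two or more methods.
    """
    if len(rankings) < 2:
        raise ValueError("overlap report needs >= 2 rankings")
    names = list(rankings)
    universes = {name: set(r.genes) for name, r in rankings.items()}
    first = universes[names[0]]
    for name in names[1:]:
        if universes[name] != first:
            raise ValueError(f"rankings {names[0]!r} and {name!r} cover "
                             "different gene universes")
    tops = {name: set(rankings[name].top(k)) for name in names}
    unique = {
        name: sorted(tops[name] - set().union(*(tops[m] for m in names if m != name)))
        for name in names
    }
    from itertools import combinations
    intersections = {}
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            shared = set.intersection(*(tops[m] for m in combo))
            intersections["&".join(combo)] = len(shared)
    return {
        "k": k,
        "top": {name: sorted(tops[name]) for name in names},
        "unique_counts": {name: len(u) for name, u in unique.items()},
        "unique": unique,
        "intersections": intersections,
    }
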