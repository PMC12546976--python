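"""Readers and writers for every external file the pipeline touches.

All inputs are plain text: a PPI edge list with per-edge confidence scores
(HIPPIE-style TSV), gene-set annotation files in GMT format, a gene x sample
expression TSV, plain one-gene-per-line lists, and the ranking TSV the
pipeline emits.  Gene identifiers are opaque tokens: they are
whitespace-trimmed, matched case-sensitively, and must share one namespace
across all inputs (the package performs no symbol/Entrez conversion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("biorank")

__all__ = [
    "PPINetwork",
    "AnnotationCatalog",
    "ExpressionMatrix",
    "RankingResult",
    "read_ppi",
    "read_gmt",
    "read_expression",
    "read_conditions",
    "read_gene_list",
    "read_ranking",
    "write_ranking",
]


class PPINetwork:
    """Undirected protein-protein interaction graph with edge confidences.

    Nodes are gene identifiers; each undirected edge carries a confidence in
    [0, 1].  Provides the first-order neighborhood N(i) and the set of genes
    at shortest-path distance exactly two, N2(i); the two are disjoint by
    construction.
    """

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges):
            raise ValueError("PPI network must not contain self-loops")
        self.graph = graph
        self._nodes = tuple(sorted(graph.nodes))
        self._index = {g: i for i, g in enumerate(self._nodes)}

    @property
    def nodes(self) -> tuple[str, ...]:
        """Deterministically ordered (sorted) node identifiers."""
        return self._nodes

    @property
    def node_index(self) -> Mapping[str, int]:
        return self._index

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def confidence(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["confidence"]

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for u, v, c in self.graph.edges(data="confidence"):
            yield u, v, c

    def neighbors(self, gene: str) -> frozenset[str]:
        """First-order neighborhood N(i)."""
        return frozenset(self.graph.neighbors(gene))

    def second_neighbors(self, gene: str) -> frozenset[str]:
        """Genes at shortest-path distance exactly 2 from ``gene``."""
        first = set(self.graph.neighbors(gene))
        second: set[str] = set()
        for u in first:
            second.update(self.graph.neighbors(u))
        second.discard(gene)
        second -= first
        return frozenset(second)


def read_ppi(path: str | Path, min_confidence: float = 0.7) -> PPINetwork:
    """Load a tab-separated PPI edge list, keeping edges whose confidence
    strictly exceeds ``min_confidence``.

    Expects >= 3 columns per line: gene A, gene B, confidence (extra columns
    ignored).  Self-loops are dropped; duplicate unordered pairs are collapsed
    keeping the maximum confidence; nodes are the endpoints of retained edges.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    best: dict[frozenset[str], float] = {}
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            try:
                conf = float(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: confidence {fields[2]!r} is not a number"
                ) from exc
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty gene identifier")
            if a == b:
                n_self += 1
                continue
            if conf <= min_confidence:
                continue
            key = frozenset((a, b))
            if conf > best.get(key, -1.0):
                best[key] = conf
    if not best:
        raise ValueError(
            f"{path}: no edges retained at confidence > {min_confidence}"
        )
    if n_self:
        logger.info("read_ppi: dropped %d self-loop record(s)", n_self)
    graph = nx.Graph()
    for key, conf in best.items():
        u, v = sorted(key)
        graph.add_edge(u, v, confidence=conf)
    net = PPINetwork(graph)
    logger.info("read_ppi: %d nodes, %d edges retained", net.n_nodes, net.n_edges)
    return net


class AnnotationCatalog:
    """Per-source term -> gene-set maps with the derived per-gene index A(i).

    ``sources`` preserves the order the GMT files were given in; A(i) is the
    set of (source, term) pairs whose gene set contains gene i.
    """

    def __init__(self, terms: Mapping[str, Mapping[str, frozenset[str]]],
                 sources: Sequence[str] | None = None):
        self.sources: tuple[str, ...] = tuple(sources if sources is not None else terms)
        self.terms: dict[str, dict[str, frozenset[str]]] = {
            s: dict(terms[s]) for s in self.sources
        }
        for source, tmap in self.terms.items():
            for term, genes in tmap.items():
                if not genes:
                    raise ValueError(f"term {term!r} in source {source!r} is empty")
        self._by_gene: dict[str, set[tuple[str, str]]] = {}
        for source in self.sources:
            for term, genes in self.terms[source].items():
                for g in genes:
                    self._by_gene.setdefault(g, set()).add((source, term))

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def annotations(self, gene: str) -> frozenset[tuple[str, str]]:
        """A(i): every (source, term) pair annotating ``gene``."""
        return frozenset(self._by_gene.get(gene, ()))

    def term_genes(self, source: str, term: str) -> frozenset[str]:
        return self.terms[source][term]

    def restricted_to(self, universe: Iterable[str]) -> "AnnotationCatalog":
        """Intersect every term with ``universe``; drop terms that empty out."""
        uni = set(universe)
        kept: dict[str, dict[str, frozenset[str]]] = {}
        dropped_genes: set[str] = set()
        for source in self.sources:
            kept[source] = {}
            for term, genes in self.terms[source].items():
                inside = genes & uni
                dropped_genes |= genes - uni
                if inside:
                    kept[source][term] = frozenset(inside)
        if dropped_genes:
            logger.info(
                "annotation catalog: dropped %d gene(s) absent from the network",
                len(dropped_genes),
            )
        return AnnotationCatalog(kept, sources=self.sources)


def read_gmt(paths: Sequence[str | Path]) -> AnnotationCatalog:
    """Load one or more GMT files as an annotation catalog, one source per
    file, in argument order.

    GMT lines are ``term<TAB>description<TAB>gene[<TAB>gene...]``.  Genes are
    deduplicated within a term; terms that end up with no genes are dropped.
    """
    if not paths:
        raise ValueError("at least one GMT file is required")
    terms: dict[str, dict[str, frozenset[str]]] = {}
    sources: list[str] = []
    for path in paths:
        source = Path(path).stem
        if source in terms:  # same stem twice: disambiguate
            source = str(path)
        sources.append(source)
        tmap: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: line {lineno}: GMT lines need term, description "
                        f"and >= 1 gene ({len(fields)} fields found)"
                    )
                term = fields[0].strip()
                genes = frozenset(g.strip() for g in fields[2:] if g.strip())
                if not genes:
                    continue
                tmap[term] = genes
        terms[source] = tmap
    catalog = AnnotationCatalog(terms, sources=sources)
    total = sum(len(t) for t in catalog.terms.values())
    if total == 0:
        raise ValueError("no annotation terms found in any GMT file")
    logger.info("read_gmt: %d source(s), %d terms", catalog.n_sources, total)
    return catalog


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix L with per-sample condition labels."""

    values: pd.DataFrame                 # genes x samples, float
    conditions: pd.Series                # sample -> "tumor" | "control"

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("expression matrix needs >= 2 genes and >= 2 samples")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated gene row(s): {sorted(dups)[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing[:5]}")
        bad = set(self.conditions.loc[list(self.values.columns)]) - {"tumor", "control"}
        if bad:
            raise ValueError(f"condition labels must be tumor/control, got {sorted(bad)}")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def sample_columns(self, which: str) -> list[str]:
        """Columns for ``which`` in {'tumor', 'control', 'all'}."""
        if which == "all":
            return list(self.values.columns)
        if which not in ("tumor", "control"):
            raise ValueError(f"unknown sample selector {which!r}")
        return [s for s in self.values.columns if self.conditions[s] == which]

    def restricted_to(self, universe: Iterable[str]) -> "ExpressionMatrix":
        uni = set(universe)
        keep = [g for g in self.values.index if g in uni]
        dropped = self.values.shape[0] - len(keep)
        if dropped:
            logger.info("expression matrix: dropped %d gene(s) absent from the network", dropped)
        return ExpressionMatrix(self.values.loc[keep], self.conditions)


def read_expression(path: str | Path,
                    condition_map: Mapping[str, str]) -> ExpressionMatrix:
    """Load a genes x samples TSV (header = sample ids, first column = gene
    ids) and attach condition labels from ``condition_map``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicated gene row(s): {dups[:5]}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing value(s) in expression matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value") from exc
    unlabeled = [s for s in df.columns if s not in condition_map]
    if unlabeled:
        raise ValueError(f"{path}: sample(s) without condition label: {unlabeled[:5]}")
    conditions = pd.Series({s: condition_map[s] for s in df.columns})
    return ExpressionMatrix(df, conditions)


def read_conditions(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>condition file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected sample<TAB>condition")
            out[fields[0].strip()] = fields[1].strip()
    if not out:
        raise ValueError(f"{path}: no condition assignments found")
    return out


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-gene-per-line list; '#' comment lines are ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            genes.add(token)
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes


@dataclass
class RankingResult:
    """Deterministic gene ranking: rank 1..n, scores non-increasing, sum 1."""

    entries: list[tuple[int, str, float]]        # (rank, gene, score)
    meta: dict = field(default_factory=dict)     # alpha, beta, d, tol, iterations...

    def __post_init__(self) -> None:
        ranks = [r for r, _, _ in self.entries]
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be 1..n with no gaps")
        scores = [s for _, _, s in self.entries]
        if any(b > a + 1e-15 for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing with rank")

    @property
    def genes(self) -> list[str]:
        return [g for _, g, _ in self.entries]

    @property
    def scores(self) -> dict[str, float]:
        return {g: s for _, g, s in self.entries}

    def top(self, k: int) -> list[str]:
        return [g for _, g, _ in self.entries[:k]]

    def __len__(self) -> int:
        return len(self.entries)


def write_ranking(ranking: RankingResult, path: str | Path) -> None:
    """Write a ranking as TSV (rank, gene, score), scores at 15 significant
    digits so a read-back reproduces the ordering exactly."""
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\n")
        for rank, gene, score in ranking.entries:
            fh.write(f"{rank}\t{gene}\t{score:.15g}\n")


def read_ranking(path: str | Path) -> RankingResult:
    """Read back a ranking TSV written by :func:`write_ranking`."""
    entries: list[tuple[int, str, float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["rank", "gene", "score"]:
            raise ValueError(f"{path}: not a ranking file (bad header {header})")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected rank, gene, score")
            entries.append((int(fields[0]), fields[1], float(fields[2])))
    if not entries:
        raise ValueError(f"{path}: empty ranking")
    return RankingResult(entries)


def restrict_seeds(seeds: Iterable[str], network: PPINetwork) -> set[str]:
    """Drop seed genes absent from the network; error if none remain."""
    seeds = set(seeds)
    kept = {s for s in seeds if s in network}
    dropped = len(seeds) - len(kept)
    if dropped:
        logger.info("seed set: dropped %d gene(s) absent from the network", dropped)
    if not kept:
        raise ValueError("no seed genes remain after restriction to the network")
    return kept
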