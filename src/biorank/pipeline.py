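"""End-to-end orchestration: files in, ranking (and optional scorecard) out.

``prioritize`` is the in-memory pipeline core; ``run_biorank`` and
``run_baseline`` wrap it with file I/O, provenance capture and debug dumps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .enrichment import compute_theta, select_significant_terms
from .expression import binarize, call_de_genes, edge_correlations, zscore
from .io import (AnnotationCatalog, ExpressionMatrix, PPINetwork, RankingResult,
                 logger, read_conditions, read_expression, read_gene_list,
                 read_gmt, read_ppi, restrict_seeds, write_ranking)
from .metrics import EvaluationReport, evaluate_ranking
from .pagerank import PageRankConfig, classic_pagerank, personalized_pagerank, rank_genes
from .weights import build_personalization, combine_edge_weights, compute_phi, \
    compute_w1, compute_w2

__all__ = ["BioRankParams", "RunConfig", "prioritize", "run_biorank", "run_baseline"]


@dataclass(frozen=True)
class BioRankParams:
    """Every tunable knob of the method, with defaults.

    alpha mixes annotation vs topological node evidence in q; beta mixes
    annotation vs co-expression edge evidence in W; c is the positive edge
    floor; ell the seed constant in theta; z_threshold the extreme-value
    cutoff; level the adjusted-significance cutoff for annotation terms.
    """

    alpha: float = 0.5
    beta: float = 0.5
    c: float = 0.1
    ell: float = 1000.0
    z_threshold: float = 2.5
    level: float = 1e-5
    pooled_bh: bool = False
    damping: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    min_confidence: float = 0.7
    zscore_columns: str = "all"      # samples feeding mu/sigma
    de_columns: str = "tumor"        # samples whose flag rates are compared
    coexpr_columns: str = "tumor"    # samples feeding Pearson correlations
    negative_corr: str = "clip"      # clip | abs
    include_seeds: bool = True
    restrict_truth: bool = False
    topk: int = 15

    def pagerank_config(self) -> PageRankConfig:
        return PageRankConfig(self.damping, self.tol, self.max_iter)


def prioritize(network: PPINetwork,
               catalog: AnnotationCatalog,
               expression: ExpressionMatrix,
               seeds,
               params: BioRankParams = BioRankParams(),
               ) -> tuple[RankingResult, dict]:
    """Run the full scoring pipeline on in-memory inputs.

    Returns the ranking plus a dict of intermediates (significant terms,
    theta, DE set, phi, node and edge bundles, raw scores) for inspection
    and debug dumps.
    """
    catalog = catalog.restricted_to(network.nodes)
    expression = expression.restricted_to(network.nodes)
    seeds = restrict_seeds(seeds, network)

    sig = select_significant_terms(catalog, seeds, network.nodes,
                                   level=params.level, pooled=params.pooled_bh)
    theta = compute_theta(catalog, sig, seeds, network.nodes, ell=params.ell)

    bexpr = binarize(zscore(expression, params.zscore_columns), params.z_threshold)
    de = call_de_genes(bexpr, expression, params.de_columns)
    phi = compute_phi(network, seeds, de)
    node_bundle = build_personalization(theta, phi, params.alpha, network.nodes)

    corr = edge_correlations(expression, network, params.coexpr_columns)
    w1 = compute_w1(network, catalog, sig.union, params.c)
    w2 = compute_w2(corr, network, params.negative_corr)
    edge_bundle = combine_edge_weights(w1, w2, params.beta, network.nodes)

    scores = personalized_pagerank(edge_bundle, node_bundle.q,
                                   params.pagerank_config())
    ranking = rank_genes(
        scores, seeds=seeds, include_seeds=params.include_seeds,
        meta={"alpha": params.alpha, "beta": params.beta, "c": params.c,
              "ell": params.ell, "damping": params.damping, "tol": params.tol})
    intermediates = {
        "significant_terms": sig,
        "theta": theta,
        "binarized": bexpr,
        "de": de,
        "phi": phi,
        "node_bundle": node_bundle,
        "correlations": corr,
        "edge_bundle": edge_bundle,
        "scores": scores,
        "seeds": seeds,
    }
    return ranking, intermediates


@dataclass
class RunConfig:
    """File-level run description; serialized verbatim into the output
    directory for provenance."""

    ppi: str
    gmt: list[str]
    expression: str
    conditions: str
    seeds: str
    truth: str | None = None
    out_dir: str = "biorank_out"
    params: BioRankParams = field(default_factory=BioRankParams)
    debug: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        param_keys = {f.name for f in dataclasses.fields(BioRankParams)}
        params = BioRankParams(**{k: v for k, v in raw.items() if k in param_keys})
        run_keys = {f.name for f in dataclasses.fields(cls)} - {"params"}
        return cls(params=params,
                   **{k: v for k, v in raw.items() if k in run_keys})

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(cfg: RunConfig, outdir: Path, created: list[Path]) -> None:
    inputs = {"ppi": cfg.ppi, "expression": cfg.expression,
              "conditions": cfg.conditions, "seeds": cfg.seeds}
    inputs.update({f"gmt_{i}": p for i, p in enumerate(cfg.gmt)})
    if cfg.truth:
        inputs["truth"] = cfg.truth
    prov = outdir / "provenance.json"
    with open(prov, "w") as fh:
        json.dump({
            "config": cfg.as_dict(),
            "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
        }, fh, indent=2, sort_keys=True)
    created.append(prov)
    snap = outdir / "config.yaml"
    with open(snap, "w") as fh:
        yaml.safe_dump(cfg.as_dict(), fh, sort_keys=True)
    created.append(snap)


def _dump_debug(outdir: Path, inter: dict, created: list[Path]) -> None:
    terms = outdir / "enrichment_report.tsv"
    with open(terms, "w") as fh:
        fh.write("source\tterm\tk\tK\tn\tN\tp\tadjusted\tretained\n")
        for r in inter["significant_terms"].records:
            fh.write(f"{r.source}\t{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p:.6g}\t{r.adjusted:.6g}\t{int(r.retained)}\n")
    created.append(terms)
    nodes = outdir / "node_weights.tsv"
    nb = inter["node_bundle"]
    with open(nodes, "w") as fh:
        fh.write("gene\ttheta\tphi\tq\tde\n")
        for i, g in enumerate(nb.nodes):
            fh.write(f"{g}\t{nb.theta[i]:.6g}\t{nb.phi[i]:.6g}\t"
                     f"{nb.q[i]:.6g}\t{int(g in inter['de'])}\n")
    created.append(nodes)


def run_biorank(cfg: RunConfig) -> tuple[RankingResult, EvaluationReport | None]:
    """Files in -> ranking.tsv (+ evaluation.json when a truth list is
    given) in ``cfg.out_dir``; partial outputs are removed on failure."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        network = read_ppi(cfg.ppi, cfg.params.min_confidence)
        catalog = read_gmt(cfg.gmt)
        conditions = read_conditions(cfg.conditions)
        expression = read_expression(cfg.expression, conditions)
        seeds = read_gene_list(cfg.seeds)

        ranking, inter = prioritize(network, catalog, expression, seeds, cfg.params)

        rank_path = outdir / "ranking.tsv"
        write_ranking(ranking, rank_path)
        created.append(rank_path)
        _write_provenance(cfg, outdir, created)
        if cfg.debug:
            _dump_debug(outdir, inter, created)

        report = None
        if cfg.truth:
            truth = read_gene_list(cfg.truth)
            report = evaluate_ranking(ranking, truth, cfg.params.topk,
                                      restrict_truth=cfg.params.restrict_truth)
            eval_path = outdir / "evaluation.json"
            with open(eval_path, "w") as fh:
                json.dump(report.as_dict(), fh, indent=2)
            created.append(eval_path)
        return ranking, report
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise


def run_baseline(cfg: RunConfig) -> RankingResult:
    """Classic PageRank over the filtered PPI graph, same output format."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        network = read_ppi(cfg.ppi, cfg.params.min_confidence)
        scores = classic_pagerank(network, cfg.params.pagerank_config())
        ranking = rank_genes(scores, meta={"method": "classic_pagerank",
                                           "damping": cfg.params.damping})
        rank_path = outdir / "ranking.tsv"
        write_ranking(ranking, rank_path)
        created.append(rank_path)
        return ranking
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise
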