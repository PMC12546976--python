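"""Generate a synthetic planted-module dataset and run the full pipeline.

The fixture plants a 25-gene disease module in a 300-gene interaction
network: the module is wired more densely, a few annotation terms are
enriched for it, and its genes are over-expressed in a subset of tumor
samples.  Eight module genes serve as seeds; the remaining seventeen are the
held-out truth the ranking should recover.
"""

from biorank import (BioRankParams, FixtureConfig, evaluate_ranking,
                     generate_fixture, prioritize)

bundle = generate_fixture(FixtureConfig(seed=1))
print(f"network: {bundle.network.n_nodes} genes, "
      f"{bundle.network.n_edges} edges")
print(f"seeds: {len(bundle.seeds)}, held-out truth genes: {len(bundle.truth)}")

params = BioRankParams(include_seeds=False)   # rank novel candidates only
ranking, inter = prioritize(bundle.network, bundle.catalog,
                            bundle.expression, bundle.seeds, params)

sig = inter["significant_terms"]
print(f"\nenriched annotation terms retained (adjusted < {sig.level:g}): "
      f"{len(sig.union)}")
print(f"differentially expressed genes: {len(inter['de'])}")

print("\ntop 15 candidates (rank, gene, propagated score, in truth?):")
for rank, gene, score in ranking.entries[:15]:
    mark = "*" if gene in bundle.truth else " "
    print(f"  {rank:3d}  {gene}  {score:.6f}  {mark}")

report = evaluate_ranking(ranking, bundle.truth, k=15)
print(f"\ntop-15 scorecard: match={report.match}  "
      f"Recall@15={report.recall:.4f}  nDCG@15={report.ndcg:.4f}  "
      f"validation rate={report.rate}%")
print("A match marks a held-out module gene recovered without being a seed;"
      "\nthe validation rate is the share of the top 15 that are true targets.")
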