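# biorank

Biologically-informed personalized PageRank for prioritizing cancer
therapeutic target genes.

Network propagation is a standard way to rank candidate disease genes:
start from a set of known disease genes (seeds) on a protein–protein
interaction (PPI) network and let a random walk with restart spread their
influence. Classic PageRank, however, sees only topology. This package
implements **BioRank**, which injects gene-level biology into both ends of
the walk:

* **Node evidence.** The teleport (personalization) vector is a convex mix
  `q = α·θ̂ + (1−α)·φ̂` of two normalized scores: θ, built from annotation
  terms (GO/KEGG/Reactome-style gene sets) significantly enriched in the
  seed set — each term tested with a one-sided Fisher exact test and
  retained when its Benjamini–Hochberg-adjusted value is below 10⁻⁵, with
  seeds themselves pinned to a large constant ℓ so they keep top priority —
  and φ, which for each differentially expressed gene measures the seed
  fraction of its first- and second-order PPI neighborhoods. Differential
  expression is a flag-rate rule: expression is z-scored per gene, values
  with z > 2.5 are flagged, and a gene is DE when its flag rate strictly
  exceeds the matrix-wide mean rate.
* **Edge evidence.** The transition kernel is a convex mix
  `W = β·Ŵ₁ + (1−β)·W₂` of two row-stochastic kernels: W₁ from the count of
  significant annotations shared by an edge's endpoints (floored at a
  constant c > 0 so no interaction vanishes), and W₂ from non-negative
  Pearson co-expression across tumor samples.
* **Propagation.** The ranking is the fixed point of
  `PR(v) = (1−d)·q(v) + d·Σ_{u→v} PR(u)·w(u,v) / Σ_k w(u,k)` with damping
  d = 0.85, found by power iteration; dangling mass teleports through q.

Input files are plain text: a HIPPIE-style PPI edge list (edges kept when
confidence strictly exceeds 0.7), GMT gene-set files, a gene × sample
expression TSV with tumor/control labels, and one-gene-per-line seed and
ground-truth lists. Rankings are scored with match count, Recall@K, nDCG@K
and the top-K validation rate.

## Worked example

A synthetic generator plants a disease module — denser wiring, seed-enriched
annotation terms, tumor over-expression — so the whole pipeline runs without
any downloads:

```sh
python examples/01_simulate_and_prioritize.py
```

```
network: 300 genes, 1500 edges
seeds: 8, held-out truth genes: 17

enriched annotation terms retained (adjusted < 1e-05): 7
differentially expressed genes: 68

top 15 candidates (rank, gene, propagated score, in truth?):
    1  G0089  0.047996  *
    2  G0041  0.033637  *
    ...
top-15 scorecard: match=15  Recall@15=0.8824  nDCG@15=1.0000  validation rate=100.0%
```

All fifteen top-ranked candidates are held-out module genes: the seeds'
annotation and expression footprint steers the walk back to the planted
module. `examples/02`–`04` walk through the enrichment scores, the edge
kernels, and the replicate benchmark against classic PageRank.

The same pipeline is scriptable from a shell:

```sh
biorank simulate --out fixture --seed 1
biorank run --ppi fixture/ppi.tsv --gmt fixture/source1.gmt \
    --gmt fixture/source2.gmt --expr fixture/expression.tsv \
    --conditions fixture/conditions.tsv --seeds fixture/seeds.txt \
    --truth fixture/truth.txt --out run1
biorank evaluate --ranking run1/ranking.tsv --truth fixture/truth.txt --k 15
```

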