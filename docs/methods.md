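# Methods

## Model

BioRank ranks genes by the stationary distribution of a personalized random
walk on a confidence-filtered PPI network. The walk restarts with
probability 1 − d into a personalization vector q that encodes node-level
biology, and otherwise steps along edges with probabilities from a kernel W
that encodes edge-level biology:

    PR(v) = (1 − d)·q(v) + d·Σ_{u ∈ B(v)} PR(u) · w(u, v) / Σ_k w(u, k)

with B(v) the in-neighbors of v. Undirected PPI edges are expanded to both
directed arcs before weighting, since the sum runs over in-neighbors.

### Node evidence

**θ (annotation score).** Every annotation term from each source is tested
for over-representation in the seed set against the network-gene universe
with a one-sided Fisher exact test (hypergeometric upper tail). P-values
are adjusted per source with Benjamini–Hochberg; terms with adjusted value
strictly below the level (default 10⁻⁵) form the reliable sets F_j and
their union F. Then θ_i = ℓ for seeds and Σ_j |A(i) ∩ F_j| / |F_j|
otherwise, where A(i) is gene i's (source, term) annotation set and sources
with empty F_j contribute 0. ℓ (default 1000) must exceed the number of
sources l — the supremum of the non-seed score — so seeds always dominate
the initialization; its exact magnitude is immaterial because θ is
normalized into q. Correcting per source rather than pooled treats each
source as its own test family, matching the per-source definition of F_j; a
pooled switch exists.

**φ (seed proximity).** For each differentially expressed gene i,
φ_i = |N(i) ∩ S| / |N(i)| + |N₂(i) ∩ S| / |N₂(i)| where N and N₂ are the
first- and exactly-second-order neighborhoods; an empty neighborhood's term
is 0, and φ is 0 for non-DE genes. Seeds that are themselves DE get φ
computed like any other gene.

**Differential expression** is a flag-rate rule. Expression is z-scored
per gene with the sample (m − 1) standard deviation over all samples
(constant rows map to z ≡ 0 and can never be flagged); elements with
z strictly above τ = 2.5 are flagged; a gene is DE when its mean flag over
the tumor columns strictly exceeds the matrix-wide mean flag over those
columns. Ties at the mean are not called. Which samples feed the z-scores
(`all`) versus the flag-rate comparison and co-expression (`tumor`) is
configurable; the defaults reflect that standardization benefits from the
control baseline while the DE and co-expression signals are tumor
phenomena.

**q = α·θ̂ + (1 − α)·φ̂** with each vector normalized to sum 1. An all-zero
φ (no DE genes near seeds) is replaced by the uniform vector so q stays a
distribution; an all-zero θ is an error, since it means no seed survived
restriction.

### Edge evidence

**W₁** puts weight c + DSI(i, j) on each arc of the PPI graph, where
DSI(i, j) = |A(i) ∩ A(j) ∩ F| counts significant annotations shared by the
endpoints and c > 0 (default 0.1) is a floor that keeps every interaction
usable when no annotation evidence exists.

**W₂** row-normalizes the non-negative Pearson correlations between each
gene and its PPI neighbors over tumor samples. Negative correlations are
clipped to 0 by default (they cannot be transition probabilities); a row
whose clipped sum is 0 falls back to the uniform distribution over its
neighbors. An absolute-value mode is available for users who regard strong
anti-correlation as evidence of interaction.

**W = β·Ŵ₁ + (1 − β)·W₂.** W₁ lives on an additive scale (entries ≥ c)
while W₂ rows already sum to 1, so W₁ is row-normalized first; β then mixes
two row-stochastic kernels and every non-dangling row of W sums to 1, which
keeps the propagation denominator stable and makes β a true balance
parameter.

### Propagation and ranking

Power iteration from x₀ = q, with the L1 stopping rule ‖x_{t+1} − x_t‖₁ <
10⁻¹⁰ and a 1000-iteration cap; exceeding the cap raises an error carrying
the final residual. Mass on dangling rows is redistributed through q each
iteration, so Σ PR = 1 holds throughout (asserted in the loop). The
ranking sorts by descending score with ties broken by ascending gene
identifier, making results bit-reproducible across runs and platforms.
Seeds are kept in the ranking by default; excluding them
(`include_seeds=False`) evaluates novel recovery.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| min_confidence | 0.7 | keep PPI edges with confidence strictly above |
| level | 1e-5 | adjusted-significance cutoff for annotation terms |
| ell (ℓ) | 1000 | seed constant in θ; any value > l works |
| τ (z_threshold) | 2.5 | extreme-expression flag cutoff |
| α | 0.5 | annotation (θ) vs topology (φ) in q |
| β | 0.5 | annotation (W₁) vs co-expression (W₂) in W |
| c | 0.1 | positive floor on annotation edge weights |
| d (damping) | 0.85 | probability of following an edge vs teleporting |
| tol / max_iter | 1e-10 / 1000 | power-iteration stopping rule |

α, β and c have no published reference values; 0.5/0.5 weighs the two
evidence channels evenly and c = 0.1 keeps the floor an order of magnitude
below one shared annotation. The sensitivity of the ranking to α and β is
an open question left to the user's grid search.

## Synthetic data

The generator emulates the statistical structure the method's evidence
channels assume, at desk scale: 300 genes, ~1500 edges (random spanning
tree plus uniform extras, so no gene is isolated), a 25-gene planted module
wired with extra intra-module probability 0.2 (denser than the ~0.024
background pair rate, but not so dense that degree alone identifies it),
8 seed genes inside the module, 40 tumor + 20 control samples, and 2
annotation sources of 50 terms each. Five terms per source are "disease
terms" drawing 90 % of their 25 members from the module — sized so that the
typical seed capture (k ≈ 7 of 8 under hypergeometric sampling) clears the
adjusted 10⁻⁵ level — and the rest are uniform background sets of 10–40
genes. Module genes gain +8 noise-sd units in 15 % of tumor samples (the
same affected patients for every module gene, which also induces
co-expression along intra-module edges); with an affected fraction p = 0.1
of all samples, the z-score of a shifted sample approaches √((1−p)/p) ≈ 3,
comfortably past the 2.5 flag threshold, while unshifted background crosses
it at the ~0.6 % Gaussian rate. The truth list is the module minus the
seeds.

What the generator does **not** emulate: RNA-seq count distributions,
library-size effects, batch structure, hub-dominated degree distributions,
or annotation-term hierarchy and redundancy. Passing the recovery benchmark
therefore shows the machinery rewards exactly the signals it was built to
reward — it does not certify performance on real tumor cohorts.

The recovery experiment compares mean Recall@10 on the held-out module
genes against classic PageRank over independent replicates, with seeds
excluded from both rankings (the truth contains no seeds; the question is
novel recovery). Its matched null sets δ = 0, enrichment = 0 **and**
module wiring = background: leaving the dense wiring in place would leave a
topological trace of the module that both methods — and the seeds sitting
inside it — could exploit, so only the fully unplanted configuration is a
genuine null. Under it, module ranks are uniform (checked with a
Kolmogorov–Smirnov test) and neither method shows a systematic advantage.

## Numerical choices

* Fisher tails come from scipy's hypergeometric survival function, which
  matches exact integer enumeration to ~10⁻¹⁵ relative error across all
  tables with N ≤ 60 (verified exhaustively in the test suite).
* "Exceeding" thresholds are strict everywhere: edge confidence > 0.7,
  z > τ, flag rate > global mean, adjusted value < level.
* Duplicate PPI records keep the maximum confidence — conservative for
  retention under a strict filter.
* Degenerate inputs: constant expression rows (z ≡ 0, never flagged),
  empty neighborhoods (φ term 0), all-negative correlation rows (uniform
  fallback), dangling nodes (teleport absorption), empty F_j (source
  contributes 0 to θ).
* Evaluation uses the truth list as given for the Recall denominator;
  restricting it to the ranked universe is available behind a flag and
  logged. Validation rates truncate to one decimal rather than round.

## Limitations

* The flag-rate DE rule detects over-expression only (z > τ is one-sided);
  down-regulated disease genes contribute nothing to φ.
* Identifier namespaces are the caller's responsibility: all inputs must
  use the same gene naming scheme, and genes absent from the PPI network
  are dropped (with logged counts) rather than mapped.
* Enrichment treats terms as flat sets — no ontology-graph propagation or
  term-redundancy pruning — so heavily overlapping terms can double-count
  in θ and DSI.
* The acceptance-scale experiments run at desk scale (hundreds of genes);
  behavior on 10⁴-node networks is covered by the algorithmic complexity
  (sparse power iteration) but not by the test suite's statistics.
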