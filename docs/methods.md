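# Methods

## Problem and model

A gene–disease association (GDA) network is an undirected bipartite graph
`G = (V, E)`: gene nodes on one side, disease nodes on the other, one edge
per curated association, optionally weighted by an evidence score
`w_ij ∈ [0, 1]` (weights default to 1; public GDA exports are effectively
unweighted, so the weight column is opt-in). Link prediction asks: given
the observed edges, which unobserved gene–disease pairs are most likely to
be true associations?

The model is a graph autoencoder. The encoder stacks two graph-convolution
layers using the symmetric normalisation with self-loops,

    Â = D̃^(−1/2) (A + I) D̃^(−1/2),   D̃ = diag((A + I)·1),

so entry `(i, j)` of `Â` is `w_ij / sqrt(d̃_i d̃_j)` and an isolated node
keeps a unit self-loop. With identity input features the forward pass is

    Z = Â · dropout(ReLU(Â · W1)) · W2,

`W1 ∈ R^(n×100)`, `W2 ∈ R^(100×50)`. Identity features are the standard
choice when nodes carry no attributes: row `i` of `W1` becomes a free
embedding for node `i`, refined by two rounds of neighbourhood averaging.
The decoder scores a pair by the inner product of its embeddings,
`p(i, j) = σ(h_i · h_j)`, computed batched via einsum.

The architecture is intentionally fixed at two layers. "Embedding
dimension 50" refers to the output width; the hidden width is an open
choice and defaults to 2× the output (100). Both matrices are
Glorot-uniform initialised from a seeded generator.

## Training

Positives are the training edges; negatives are gene–disease non-edges
sampled uniformly, 1:1 with positives, resampled every epoch so no single
negative set is memorised. The loss is binary cross-entropy on the decoded
probabilities,

    L = −mean log p(pos) − mean log(1 − p(neg)),

with probabilities clamped to `[1e−15, 1 − 1e−15]` (this realises
"minimise the difference between A and the reconstruction A′" as balanced
edge classification, the standard graph-autoencoder reading). Optimisation
is full-batch Adam (lr 0.01, β = (0.9, 0.999)); gradients are derived in
closed form and verified against central finite differences in the test
suite. A non-finite loss aborts with a diagnostic rather than silently
continuing. Dropout (p = 0.5) is inverted — survivors scaled by
`1/(1 − p)` — so activations are unbiased; it is applied between the two
layers during training only. A fixed seed makes runs bitwise reproducible
on one thread (weight init, dropout masks and negative sampling all derive
from it).

## Splits and leakage control

`split_edges` withholds `round(0.05·m)` validation and `round(0.10·m)`
test positives uniformly at random, and samples disjoint 1:1 negative
links for each held-out set. The message-passing adjacency is built from
training positives only, and per-epoch training negatives exclude the
held-out negative pools; nothing the optimiser touches overlaps the
evaluation sets. The proportions and the 1:1 ratio are declared defaults
(standard graph-autoencoder practice), not values estimated from data.

## Evaluation

All metrics are first-principles implementations (scikit-learn appears
only as a cross-check oracle in tests):

* ROC with the prediction rule `score ≥ t ⇒ positive`, one operating point
  per distinct score (ties collapse), plus the (0, 0) corner at `t = +∞`.
* AUC by the trapezoid rule, which under tie collapsing equals the
  Mann–Whitney statistic with ties credited ½.
* Average precision as the step sum `Σ (R_n − R_{n−1}) P_n` over the
  ranked list; precision at zero predicted positives is defined as 1
  (affects only the curve endpoint).
* Youden's best threshold maximises `J = TPR − FPR` over operating points;
  ties break toward the higher (more conservative) threshold. The
  threshold is selected on validation scores so test data stay untouched;
  in the degenerate all-tied case the maximising point is the (0, 0)
  corner and the returned threshold is `+∞` with `J = 0`.

Ranking uses raw dot products (Top-k, default 15, exact selection with
lexicographic `(gene_id, disease_id)` tie-breaks); thresholding uses
logistic probabilities. The two orderings coincide because the logistic is
strictly monotone. The candidate universe is every gene × disease non-edge
of the full input graph, scored in bounded-memory blocks of the score
matrix; callers may exclude further pairs (e.g. associations known from a
larger reference export). A diagnostic reports the mean degree of Top-k
endpoints against the graph mean, quantifying the hub bias expected of
convolutional embeddings; it is reported, not asserted, since its size is
instance-dependent.

## Synthetic data

`generate_block_bipartite` plants `k` latent blocks: genes and diseases
are assigned uniformly, matched-block pairs connect with `p_in`, unmatched
with `p_out`, every pair independently. Optional `degree_skew` multiplies
probabilities by per-node propensities `u^(−1/(1+skew))` (u uniform,
normalised to mean 1, products capped at 1), producing the heavy-tailed,
hub-dominated degrees of real curated networks. `generate_er_bipartite` is
the structureless null. Both refuse to emit graphs with fewer than 10
edges (untrainable) and are seed-reproducible.

What the generator does *not* emulate: evidence-score weights, correlated
block memberships (real disease modules overlap), and the scale of full
curated exports (10^4–10^6 edges). Passing the synthetic benchmark shows
the pipeline recovers planted homophily and does not hallucinate signal
from noise; it does not certify accuracy on any particular real resource.

## Benchmark problem sizes

The packaged benchmark uses a 400 × 300 planted-block graph (4 blocks,
p_in = 0.15, p_out = 0.005, ≈ 4.9k edges, generator seed 7) with five
split/model seeds at the default 100 epochs, a density-matched
Erdős–Rényi null of the same shape, and 300-epoch runs for the
overfitting-trend check — sizes chosen so a complete benchmark sweep runs
in about a minute on one CPU while leaving the block structure clearly
recoverable.

A note on the attainable AUC at this size: with homogeneous within-block
probabilities, all matched-block pairs are statistically exchangeable, so
the Bayes-optimal ranker reduces to the block-match indicator. Its AUC on
uniformly sampled negatives is ≈ 0.84 for these parameters (a ground-truth
block oracle measures 0.836 on the actual splits), and the trained model
reaches the same value — i.e. it extracts essentially all recoverable
structure. Larger block contrast or degree heterogeneity raises the
ceiling; the benchmark keeps the parameters fixed and reports the measured
value.

## Numerical choices and edge cases

* Probabilities clamped at 1e−15 in the loss; the logistic is evaluated in
  its numerically stable split form.
* Duplicate (gene, disease) records collapse to one edge keeping the
  maximum weight; edge order follows first appearance so writing and
  re-reading an edge list reproduces the identical indexing.
* An identifier appearing in both partitions is a hard error — it would
  make bipartiteness ambiguous.
* Degree-table ties break lexicographically by node id.
* Negative sampling rejects collisions on sparse graphs and switches to
  exact enumeration of the free pool when the request exceeds half the
  remaining non-edges; a request larger than the pool is an error (e.g. a
  complete bipartite graph has no negatives at all).

## Known limitations

* Full-batch training holds one dense `n × hidden` weight matrix; very
  large exports (10^5+ nodes) would need mini-batching or sparse first
  layers, out of scope here.
* No early stopping: the epoch budget is a parameter, and long runs are
  expected to plateau rather than improve (the benchmark checks this
  trend).
* The model is purely topological; association evidence scores, node
  attributes, and cross-ontology structure are ignored even when present.
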