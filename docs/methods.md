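# Methods

## Model

### Knowledge-graph convolution

The knowledge graph is a multigraph of typed entities (drug, protein, gene,
disease) connected by relation-labeled triples. The neighbor view is
**undirected** by default: each stored triple (h, r, t) contributes (r, t)
to h's adjacency and (r, h) to t's, so protein/gene/disease context reaches
drug nodes during aggregation regardless of how the triples were oriented in
the source files. A directed view is available (`directed=True`) for graphs
where orientation is meaningful. Self-loops are rejected at load: an
entity's own embedding enters through the aggregator, not its neighbor list.

An entity's representation is built from an H-hop receptive field (defaults
H = 2, N = 7 neighbors per hop). At each hop, N neighbors are sampled
uniformly — without replacement when the degree allows, with replacement
otherwise, so receptive fields are always shape-regular. Attention over the
sampled set uses softmax-normalized inner products between the *query*
entity's base embedding and the edge-relation embeddings; the attended
neighborhood mix is combined with the entity's current vector by one of
three aggregators (sum / concat / neighbor; default concat,
σ(W[e ‖ mix] + b)). Inner layers use the rectifier; the final layer uses
tanh so that exported representations are bounded, which stabilizes the
inner-product pair score downstream. Receptive fields are resampled every
epoch during training (a mild regularizer); at export time sampling is
frozen by the config seed so exports are reproducible.

The pre-training objective is deliberately simple: for each labeled pair
(a, b), score σ(⟨rep(a|query=b), rep(b|query=a)⟩) and minimize binary
cross-entropy with Adam (lr 0.005, batch 256, 12 epochs with early stop
after 5 non-improving epochs). Embeddings are exported per drug with
query = the drug itself, making the exported vector pair-independent; a
per-partner aggregation hook exists but is not the default.

### Neural factorization machine

Pair features are the concatenation [fp(a) ‖ fp(b) ‖ emb(a) ‖ emb(b)]
(2(B+d) dims; 2176 at B = 1024, d = 64). Binary fingerprint bits exploit the
sparse skip in the embedding layer {xᵢvᵢ | xᵢ ≠ 0}; the continuous embedding
block enters as-is via xᵢvᵢ. Bi-interaction pooling is computed by the
algebraic identity ½[(Σu)² − Σu²], verified in tests against the explicit
O(n²) loop. The hidden stack is 4 × 128 rectifier layers (latent width
k = 64, bi-interaction dropout 0) with a sigmoid prediction head; training
uses Adam at lr 0.005, batch 1024, 20 epochs. Since a DDI is an unordered
relation, both orderings of every training pair are emitted, and inference
averages the two ordered scores — approximate symmetry without
architectural constraints. The type classifier (Task 2) is a 512/256/128/64
feedforward network, rectifier on the first three layers, identity on the
fourth, and a softmax head over {increase, decrease}; batch size 1250.

Both trainers run on `kgddi._autograd`, a ~300-line tape-based reverse-mode
autodiff over NumPy written for this package. Every operation's gradient is
checked against central finite differences in the test suite; embedding
lookups backpropagate by segment-sum (sort + `reduceat`), and shared weight
matrices applied to batched activations accumulate their gradient with a
single `tensordot` contraction.

### Reliable negatives

Positives' pair fingerprints (canonical order: smaller drug id first, so
the rule is order-invariant) are averaged into a 2B-dimensional cluster
center. Every unlabeled pair's Euclidean distance to the center is computed;
AED is their mean, and pairs with distance **strictly greater** than
D = n × AED (default n = 1.2) become reliable negatives. Boundary-equal
pairs are not selected. The working negative set is then a uniform 1:1
subsample against the positive count; if the reliable pool is smaller than
requested the run proceeds with all of it and a logged warning rather than
silently lowering n.

**Known artifact.** Because the rule filters on *features*, the selected
negatives are fingerprint-separable from the positives *by construction* —
even in a world with no interaction signal at all, a model trained on
PU-selected negatives scores far above chance simply by learning the
selection filter. Null
calibration must therefore be run with random negatives, and reported
performance under PU selection should be read as conditional on the
selection protocol. This is inherent to distance-rule PU selection, not an
implementation defect.

## Evaluation

Point metrics (Acc, Sen, Spe, Pre, F1, MCC) come from the confusion matrix
at threshold 0.5; undefined ratios (zero denominators) are reported as NaN,
excluded from aggregates, and counted. AUROC is the rank statistic with
midranks for ties; AUPR is precision–recall step integration (both via
scikit-learn, cross-checked in tests against exhaustive concordant-pair
counting). Aggregates are mean and RSD(%) = 100·sd/mean across folds.

Stratified k-fold CV (default k = 10) operates on pairs. Pairwise-disjoint
CV partitions *drugs*: test pairs have both drugs inside the held-out drug
fold, train pairs have both outside, and straddling pairs are discarded for
that fold (counts logged). Train/test drug disjointness is asserted at
runtime, not just tested. A `one-unseen` variant keeps pairs with at least
one held-out drug in the test set. KGCN embeddings are re-learned inside
every fold on the fold's training pairs only (`cv.embeddings=per-fold`), so
no information about test pairs leaks through pre-training; a `frozen` mode
trains once on all labeled pairs for cheap exploratory runs and is labeled
as leaky in reports.

## Synthetic worlds

The generator emulates a curated pharmacology KG at reduced scale: four
entity types, eight relation types (drug–target, drug–enzyme, drug–gene,
drug–disease, drug–drug structural analogs, protein–protein,
protein–disease, gene–disease). Each drug has a hidden latent vector around
one of four cluster prototypes arranged as a regular simplex in the latent
coordinates orthogonal to a designated "type" coordinate. Three observable
channels all derive from the same latents:

* **Edges**: drugs select anchor entities by softmax over latent similarity;
  anchors wire among themselves within clusters.
* **Fingerprints**: per-cluster random bit patterns, each bit flipped
  independently (default 0.08); a trailing block of 6 bits encodes the sign
  of the type coordinate. At flip probability 0.5 the bits carry no cluster
  information (verified by an empirical mutual-information test).
* **Labels**: pair (a,b) is truly positive with probability
  σ(β(⟨z_a, z_b⟩ + e_a + e_b − τ)), flipped at the label-noise rate
  (default 0.10). Only half of the noisy positives are revealed as labeled;
  the rest join the unlabeled pool, creating the PU setting.

Design choices that matter and why:

* **Skewed clusters + one "active" cluster** (weights 0.65/0.15/0.10/0.10;
  prototype norms 1.3 vs 0.6; offset τ = 1.0): positives are then
  concentrated around one fingerprint pattern — the premise of the
  distance-based negative-selection rule. With equal clusters the far tail
  of the distance distribution consists of *minority-cluster positives* and
  the rule selects exactly the wrong pairs.
* **Hidden per-drug activity e_i** (sd 0.4): visible neither in fingerprints
  nor in KG wiring, so it can only be learned from a drug's recurrence
  across training pairs. This is the signal component cold-start splits
  remove, and it is why pairwise-disjoint CV scores below 10-fold CV here,
  and why the combined model outperforms the fingerprint-only ablation.
* **β = 0 null**: the label rule degenerates to a fair coin, giving the
  no-signal calibration world.

Defaults: 300 drugs, 120 proteins, 80 genes, 60 diseases, ≈5700 triples,
5000 candidate pairs (75% sampled within-cluster), 64-bit fingerprints at
synthetic scale. What the generator does **not** emulate: realistic degree
distributions, chemistry-valid structures, correlated bit patterns within
fingerprint families, or finer interaction typing — passing tests on this
world demonstrates that the pipeline recovers planted statistical structure
of the stated form, not performance on curated pharmacology data.

## Numerical and procedural choices

* Single master seed; per-stage seeds derive by stage-name hashing (CRC32),
  so stages can be re-run in isolation and full runs are bitwise
  reproducible (replay from a run manifest is tested byte-for-byte).
* Softmax attention is max-stabilized; the logistic is computed via the
  tanh identity (overflow-free in both tails); BCE guards log(0) with 1e−12.
* Glorot-uniform initialization for weight matrices; N(0, 0.1) for entity
  and relation tables; N(0, 0.01) for NFM latents; zeros for biases and
  linear terms.
* Study-condition runs use one CV repeat at the 300-drug scale (the harness
  supports repeated CV; `evalx.kfold_plan` defaults to 10 repeats matching
  the usual reporting protocol). Cold-start runs use 5 drug-folds.

## Limitations

* The KGCN pre-training objective (pair BCE on the inner-product score) is
  one reasonable choice among several; translational or semantic-matching
  objectives are out of scope.
* Interaction typing is binary (increase/decrease); finer clinical types
  are not modeled.
* The per-drug fingerprint file dialect supports externally computed
  fingerprints (MACCS, PubChem, …) but the package only computes hashed
  circular fingerprints itself.
* At realistic KG scale (10⁶ triples) the NumPy trainers are CPU-bound;
  the architecture ports directly to a GPU framework, but that is not
  included.
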