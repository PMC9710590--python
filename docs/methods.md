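# Methods

## Data model

The package operates on consensus *signed causal edges*. An expression edge
regulator → target with sign +1 (−1) states that activating the regulator
increases (decreases) the target's expression; a gene → function edge
states that the gene promotes or suppresses a biological function or
disease. A stored edge never has sign 0 — absence of an edge encodes "no
known effect". Duplicate edge rows with conflicting signs are dropped: the
inputs are expected to carry consensus signs, and without per-finding counts
no majority can be formed, so "no edge" is the conservative reading.

Functions live in a hierarchy (a DAG of child → parent links). Parents
inherit gene associations from their descendants: an entry without direct
curation receives the consensus sign of the descendants' entries, and 0 when
they disagree. Direct curated entries are never overwritten — that keeps the
propagation idempotent, and a curated parent sign is itself already a
consensus. Terms listed as `excluded_roots` (very general terms like
"disease") do not inherit; which terms count as too general is left to
configuration because it is a property of the ontology at hand.

## Gene embeddings

All three methods start from the N × M signed bi-adjacency matrix

    W_ij = s_ij / sqrt(N_i),   N_i = sum_j |s_ij|.

The square-root normalization is forced by requiring the signed similarity
S = W Wᵀ to have unit diagonal: rows of W are unit vectors, so S_ik is the
signed cosine overlap of two downstream regulation patterns (identical
patterns +1, exactly opposite ones −1, disjoint targets 0).

**E1 (spectral).** Truncated SVD W ≈ U Σ Vᵀ with K columns; gene embeddings
are the rows of the orthonormal U. A dense SVD is used below 10⁶ matrix
cells, a sparse iterative solver (tolerance 1e−10) above. Each column of U
is oriented so its largest-magnitude entry is positive — scores are
invariant to column signs; the convention only makes serialized embeddings
byte-reproducible. Within degenerate (tied) singular subspaces the solver's
basis is accepted as is.

**E2 (neural).** One-hot (N) → linear without bias → embedding (K) → linear
with bias + ReLU → hidden (default 1000) → linear without bias → output
(M), trained with MSE against the rows of W. The bias-free input and output
layers preserve the sign symmetry: negating an embedding vector exactly
negates the linear part of its reconstruction. The trainer is full-batch
gradient descent with adaptive-moment updates (rate 1e−3 by default; the
small dense problems in this package converge faster at 1e−2), early
stopping on a 50-epoch loss plateau. Optimizer, initialization (scaled
Gaussian) and epoch budget are package choices; only the architecture is
constrained by the model. At the scales this package targets the training
loop is a handful of dense matrix products per epoch and runs on a CPU in
seconds, so it is written directly in numpy.

**E3 (graph).** The coregulation z-score between regulators i, k is

    z_ik = (sum_j s_ij s_kj) / sqrt(N_ik),   N_ik = sum_j |s_ij||s_kj|.

Under a random-sign null the summands are ±1 with unit variance, so the
1/√N_ik scaling gives z unit variance — which is what makes it a z-score;
|z| ≥ 1.5 keeps an edge (default cutoff). Signs are encoded losslessly by
replicating each node into a u- and a v-copy: positive edges connect copies
in parallel, negative ones crosswise, so anti-similar genes co-occur with
each other's opposite replica. The replicated graph is embedded by uniform
random walks (length 30, 100 per node, return and in-out parameters p = q =
1; walks are unweighted — edge weights are not used) and skip-gram with
negative sampling (window 10, 5 negatives, 5 epochs, initial rate 0.025
with linear decay). The skip-gram trainer is a vectorized numpy loop;
within a mini-batch the accumulated gradient of each embedding row is
averaged over the row's occurrences, so a node appearing many times in one
batch takes a single learning-rate-sized step instead of a summed
(divergent) one. The u-replica vectors are returned as gene embeddings (the
two replicas are symmetric by construction). Genes isolated at the chosen
cutoff get no embedding and are excluded from downstream scoring with a
logged count.

## Function embeddings and scoring

For function j with signed association column y_j, the embedding minimizes
sum_i (x_i · p_j − Y_ij)², i.e. p_j = (UᵀU)⁻¹Uᵀy_j, computed with the
orthonormal shortcut Uᵀy_j whenever UᵀU = I to 1e−10. Prediction is treated
as regression, not classification: the values −1, 0, +1 are ordered. An
ill-conditioned UᵀU (condition number > 1e12) raises an error advising a
lower K rather than silently regularizing. Vectors are normalized
(p̃_j = p_j/‖p_j‖) so that isotropically random gene embeddings would give
every function the same score distribution; all-zero vectors (functions
with no usable gene associations) are flagged and excluded.

The gene–function score is s_ij = p̃_j · x_i. Scores are exactly
antisymmetric under negation of either vector. The z-score uses the
analytic isotropic null: a random unit function vector gives gene i a score
with standard deviation ‖x_i‖/√K, hence z_ij = s_ij √K / ‖x_i‖. An
empirical alternative (per-function column standardization) is available
behind a flag; the analytic form is the default because it is exact under
the same isotropy assumption that motivates the normalization of p̃ and
needs no estimation. Cosine similarity between functions is the dot product
of normalized vectors; its 2σ significance threshold in K dimensions is
2/√K (a component of a random unit vector has variance 1/K).

## Latent-relationship analyses

Compositional functions ("process of context") are examined by projecting
their embedding vectors on the top-2 principal components (mean-centered,
no variance scaling — the vectors are already unit length; normalized
vectors are used rather than raw ones). If function pairs differing only in
the process share an additive offset, the segments joining them are
parallel in this plane. Parallelism is tested by permutation: the statistic
is the spread of segment angles with the horizontal, where angles are taken
modulo π (segments are undirected) and the spread is the circular SD on
doubled angles. A plain standard deviation of angles in [0, π) would be
discontinuous at the wrap-around (segments at 0.01 and π − 0.01 are nearly
parallel but numerically far apart); the axial circular SD handles this and
is exactly 0 for perfectly parallel segments. The null shuffles
b-endpoints among pairs (pure permutation, no replacement), and
p = (1 + #{shuffled SD ≤ observed}) / (1 + permutations), so the smallest
attainable p is 1/(1 + permutations) and p is uniform under the null.

The disease map reduces disease vectors to 20 dimensions by exact PCA and
lays them out in 2-D with t-SNE. The PCA stage is deterministic and tested
against an eigendecomposition oracle; the t-SNE layout is stochastic but
reproducible from its seed and only smoke-tested.

## Cross-validation protocol

Balanced test sets mask n entries with value +1, n with −1 and 2n zeros,
restricted to hierarchy leaves supported by at least 10 genes (masking a
parent would leak through its children). Zero cells are sampled uniformly
over eligible (gene, leaf) positions. Gene embeddings depend only on the
expression graph, which masking does not touch, so only the per-function
regression is refit per replicate. Zeros are treated as negatives; the rare
genuinely-false negatives among them are assumed not to move the metrics.
Two tasks are scored: absolute prediction (|s| over all 4n entries, label
"entry nonzero") and sign prediction (s over the 2n nonzero entries). The
ROC of inhibition-vs-activation is the activation ROC reflected through the
anti-diagonal. Metrics are trapezoidal AUC and precision at the smallest
achieved recall ≥ 5%; when several thresholds achieve that recall the
strictest (highest-precision) one is reported. Replicate curves are
averaged vertically on a fixed 101-point grid (linear interpolation);
replicates are drawn independently (they may overlap).

## Disease networks

For a disease, genes are ranked by |z| against its vector (ties broken
lexicographically) and functions by |cosine similarity| to it — the
package's function–function instrument; the network keeps the top 15 genes
and top 20 functions by default. Function redundancy is pruned two ways:
a candidate that is an ontology ancestor of a higher-ranked retained
function is dropped (specific terms beat general ones), and within a
context bundle (equal `context` string, e.g. the same cell type) only the
top scorer survives. Edges require |z| > 3 *and* sign consistency
(sign(z) = gene sign × function sign); each edge carries provenance —
"known" if the association is present in Y, "inferred" otherwise. No
additional |z| floor is applied to gene node inclusion beyond the top-15
rank. Negating the disease vector flips every node sign and leaves the edge
set unchanged.

## Drug extension

Drugs with curated expression effects enter the bipartite graph as extra
regulator rows and receive embeddings from the same pipeline. Per disease,
a one-hidden-layer MLP (200 nodes) is trained on drug vectors: positives
are the disease's known drugs, negatives an equal-size random draw from all
other drugs (other diseases' positives are not excluded), 70/30 split,
repeated 100 times by default with a fresh negative draw and split each
repeat. The MLP is trained with L-BFGS and L2 penalty 0.1: positive sets
number tens of drugs, and full-batch quasi-Newton optimization is the
reliable regime at that sample size (stochastic optimizers need far more
data to converge and fail silently here).

## Synthetic data

The generator emulates the statistical shape of curated content with a
planted latent-factor model: regulators, targets, functions and drugs carry
i.i.d. standard-normal latent vectors in d dimensions (default 10). Edges
exist i.i.d. with probability `density`; an emitted edge gets sign
sign(g_i·t_j + b), with the scalar offset b calibrated by bisection so the
positive:negative ratio is 2:1, matching the imbalance of curated
expression content. A latent-factor model (rather than, say, a stochastic
block model) is chosen because the spectral and neural methods assume
low-rank structure in W — parameter recovery is then a meaningful test of
the whole pipeline. Each function's associated genes are the
`genes_per_function` (default 20) genes with largest |g·f|, signed by the
dot product; signs flip with probability `noise_rate`. Drugs are labeled
positive for a disease when their latent score passes the 80th-percentile
threshold, and the drugs passing it additionally share a mechanism
component along the disease axis (effect size 1.0 latent units — one
population SD of the disease score): drugs indicated for the same disease
act through common mechanisms, and that coherence is exactly what makes an
indication learnable from expression signatures. All stages are
reproducible from a single integer seed via independent child generators.

What the generator does **not** emulate: per-edge literature finding
bundles and citation-count heterogeneity, degree heavy tails (edges are
i.i.d., so regulator degrees are binomial), correlated curation bias
(well-studied genes having denser rows), and ontology depth (generated
functions are flat leaves unless an ontology is supplied). Tests passing on
this generator therefore demonstrate correct mechanics and recoverability
of low-rank signal, not performance on curated content.

## Problem sizes and numerical choices

The test and acceptance runs use N = 500 regulators, M = 2000 targets,
d = 10, density 0.05, K = 25, with n = 50 masked entries per class and
k = 10 replicates — a deliberate scale-down that keeps every run in
seconds while leaving all rates and ratios at their defaults. Tolerances:
orthonormality and SVD reconstruction 1e−8; regression vs. normal-equations
oracle 1e−10; exact (bit-level) equality for score antisymmetry and
replication losslessness. Degenerate inputs: regulators without edges must
be filtered before W is built (error); K above the numerical rank leaves
zero trailing singular values with a warning; empty similarity graphs and
all-zero function columns are flagged and logged, not fatal.

## Known limitations

* Embeddings are estimated from one-bit (sign-only) observations; with
  ~100 edges per regulator the recovered vectors carry substantial angular
  noise. On planted data at the scale above, absolute-prediction AUC
  plateaus around 0.8 even without label noise (sign prediction is near
  perfect); doubling the edges per regulator pushes it past 0.9. Absolute
  prediction quality is information-limited by graph density, not by the
  estimator — scoring with the true latent vectors on the same splits gives
  AUC ≈ 0.99.
* E3 covers only genes with at least one surviving similarity edge; at
  strict cutoffs many genes receive no embedding.
* The skip-gram and autoencoder trainers are single-threaded numpy; they
  are sized for knowledge-graph scale (thousands of regulators), not
  web-scale graphs.
* Function terms with very few associated genes yield unstable embedding
  directions; the cross-validation protocol's 10-gene support floor exists
  for this reason.
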