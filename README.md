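# causalemb

Signed cause–effect embeddings of genes, biological functions, diseases and
drugs from literature-curated causal expression relationships.

## The problem

Curated biomedical knowledge graphs contain large numbers of *signed causal
edges*: "activating gene A increases the expression of gene B" (+1) or
"decreases it" (−1), and likewise "gene A promotes / suppresses function or
disease F". Collectively these edges are a fingerprint of what each gene
does to the system. `causalemb` turns them into vector embeddings that

* predict and prioritize signed gene–function and gene–disease
  associations (activation vs inhibition, not just association),
* expose hidden relationships between functions and diseases through
  cosine similarity in embedding space,
* assemble disease-centric networks of the top-scoring genes and functions,
* extend to drug molecules, whose embeddings feed a small neural network
  predicting drug–disease associations.

It is aimed at computational biologists who have (or can simulate) signed
regulator → target edge lists and signed gene → function associations.

## The model

From the bipartite expression graph *G* (N regulators × M targets, edge
signs s<sub>ij</sub> ∈ {−1, +1}) define the row-normalized matrix

> W<sub>ij</sub> = s<sub>ij</sub> / √N<sub>i</sub>,  N<sub>i</sub> = Σ<sub>j</sub> |s<sub>ij</sub>|,

so the signed gene–gene similarity S = W Wᵀ has unit diagonal. Three
embedding methods are provided:

* **E1 (spectral)** — truncated SVD, W ≈ U Σ Vᵀ; the rows of the
  orthonormal N × K matrix U are the gene embedding vectors
  (`spectral_embed`).
* **E2 (neural)** — the same bottleneck as a small autoencoder with one
  extra bias + ReLU hidden layer (default 1000 nodes), trained with MSE
  against the rows of W; embeddings are the first-layer weights
  (`train_neural_embedding`). Input and output layers carry no bias, so
  negating an embedding exactly negates the linear part of its predicted
  regulation pattern.
* **E3 (graph)** — a signed coregulation graph H with z-scores
  z<sub>ik</sub> = Σ<sub>j</sub> s<sub>ij</sub>s<sub>kj</sub> / √N<sub>ik</sub>
  (edge kept when |z| ≥ 1.5), encoded losslessly into an unsigned graph by
  node replication (positive edges wire replicas in parallel, negative ones
  crosswise) and embedded by random-walk skip-gram (`graph_embed`).

For each function j with signed gene association column y<sub>j</sub>, the
function embedding is the least-squares solution
p<sub>j</sub> = (UᵀU)⁻¹Uᵀy<sub>j</sub> (= Uᵀy<sub>j</sub> for E1), normalized
to p̃<sub>j</sub> = p<sub>j</sub>/‖p<sub>j</sub>‖. The gene–function score is
s<sub>ij</sub> = p̃<sub>j</sub>·x<sub>i</sub>; its z-score against an
isotropic random-function null is z<sub>ij</sub> = s<sub>ij</sub>√K/‖x<sub>i</sub>‖.
Function–function similarity is the cosine p̃<sub>a</sub>·p̃<sub>b</sub>, with
2σ significance threshold **2/√K** (≈ 0.09 at K = 500).

A synthetic-data module plants a low-dimensional latent structure (genes,
targets, functions and drugs all carry latent vectors; edge signs are
sign(g·t + b) with b calibrated to the 2:1 positive:negative imbalance of
curated content) so that the entire pipeline is testable without access to
any proprietary knowledge base.

## Worked example

```python
import causalemb as ce

model = ce.LatentModel(n_genes=200, n_targets=1000, n_functions=100,
                       d=10, density=0.05, noise_rate=0.0, seed=7)
graph, _ = ce.generate_expression_graph(model)
W = ce.build_weight_matrix(graph)
emb = ce.spectral_embed(W, K=25)
Y = ce.generate_function_associations(model, genes_per_function=20,
                                      genes=graph.regulators)
F = ce.fit_function_embeddings(emb, Y)
S = ce.score_zscores(ce.score_genes(emb, F), emb)

print(f"graph: {graph.n_regulators} regulators, {graph.n_targets} targets, "
      f"{len(graph.edges)} signed edges")
print(f"cosine significance threshold at K=25: "
      f"{ce.similarity_threshold(25):.3f}")

sets = ce.make_test_sets(Y, ce.Ontology(), n=30, k=10, min_genes=10, seed=7)
report = ce.run_cross_validation(emb, Y, sets)
for name, stats in report.summary().items():
    print(f"{name}: {stats['mean']:.3f} +- {stats['sd']:.3f}")

dis = Y.functions[0]
print("top genes for", dis, ":", ce.top_disease_genes(dis, S, n_genes=5))
```

prints

```
graph: 200 regulators, 1000 targets, 9845 signed edges
cosine significance threshold at K=25: 0.400
auc_abs: 0.626 +- 0.058
prec_abs: 0.845 +- 0.163
auc_sign: 0.918 +- 0.026
prec_sign: 0.967 +- 0.100
top genes for f00000 : [('g00097', -1), ('g00139', 1), ('g00131', -1), ('g00117', -1), ('g00075', -1)]
```

`auc_abs`/`prec_abs` measure *absolute* prediction (does a causal relation
exist?) over balanced held-out sets of masked matrix entries; `auc_sign`/
`prec_sign` measure *sign* prediction (activation vs inhibition) among the
held-out nonzero entries. Precision is reported in the low-recall limit
(5%), i.e. for the very top-scoring predictions. The top-gene list pairs
each gene with the sign of its predicted effect on the disease (here the
signal is planted, so the signs match the latent ground truth).

The same pipeline is scriptable from the shell:

```bash
causalemb simulate --n-genes 200 --n-targets 1000 --seed 7 --out-dir data/
causalemb embed spectral --in data/expression_edges.tsv --out emb.tsv --dim 25
causalemb crossval --model spectral --dim 25 \
    --edges data/expression_edges.tsv \
    --associations data/gene_function.tsv \
    --n 30 --k 10 --seed 7 --out cv.json
causalemb network --disease f00000 --edges data/expression_edges.tsv \
    --associations data/gene_function.tsv --dim 25 --out net.json
```

Every command writes a manifest (parameters, input hashes, seed, version)
next to its outputs.

## Documentation

See `docs/methods.md` for the modeling assumptions, parameter defaults,
what the synthetic generator does and does not emulate, and known
limitations.
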