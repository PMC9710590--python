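"""Drug embeddings and drug–disease prediction.

Drugs that regulate gene expression enter the embedding model exactly like
regulator genes: their signed expression edges become additional rows of
the bipartite graph, so the same pipeline yields drug embedding vectors in
the same space. A small multilayer perceptron (one hidden layer, default
200 nodes) is then trained per disease on the drug vectors: positives are
the drugs known to target the disease, negatives an equal-size random draw
from the remaining drugs, with a 70/30 train/test split. Training and
testing are repeated (default 100 times, fresh negatives and split each
repeat) and ROC / precision–recall curves are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

from .embed_neural import train_neural_embedding
from .embed_spectral import (EmbeddingMatrix, build_weight_matrix,
                             spectral_embed)
from .evaluation import (PRCurve, ROCCurve, auc, average_curves_prc,
                         average_curves_roc, roc_prc)
from .knowledge_model import CausalGraph, Entity, SignedEdge

logger = logging.getLogger(__name__)

DEFAULT_HIDDEN = 200
DEFAULT_SPLIT = 0.7
DEFAULT_REPEATS = 100
MIN_POSITIVES = 10


def merge_drug_edges(G: CausalGraph, drug_edges: list[SignedEdge]
                     ) -> CausalGraph:
    """Expression graph with drugs added as extra regulator rows."""
    drug_ids = sorted({e.source for e in drug_edges})
    overlap = set(drug_ids) & set(G.regulators)
    if overlap:
        raise ValueError(f"drug ids collide with regulators: {sorted(overlap)[:5]}")
    regulators = sorted(set(G.regulators) | set(drug_ids))
    targets = sorted(set(G.targets) | {e.target for e in drug_edges})
    entities = dict(G.entities)
    entities.update({d: Entity(d, kind="drug") for d in drug_ids})
    return CausalGraph(regulators, targets,
                       list(G.edges) + list(drug_edges), entities)


def embed_with_drugs(
    G: CausalGraph,
    drug_edges: list[SignedEdge],
    method: str = "E1",
    K: int = 25,
    seed: int = 0,
    **kwargs,
) -> EmbeddingMatrix:
    """Embed genes and drugs together; drug rows obey the same unit-norm
    weighting as gene rows."""
    merged = merge_drug_edges(G, drug_edges)
    W = build_weight_matrix(merged)
    if method == "E1":
        return spectral_embed(W, K)
    if method == "E2":
        return train_neural_embedding(W, K, seed=seed, **kwargs).embedding
    if method == "E3":
        from .embed_graph import graph_embed
        emb, _ = graph_embed(merged, K, seed=seed, **kwargs)
        return emb
    raise ValueError(f"unknown embedding method {method!r}")


@dataclass
class DrugPredictionReport:
    aucs: np.ndarray
    roc_grid: np.ndarray
    roc_mean: np.ndarray
    roc_sd: np.ndarray
    prc_grid: np.ndarray
    prc_mean: np.ndarray
    prc_sd: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std())


def train_drug_mlp(
    emb: EmbeddingMatrix,
    positives: set[str] | list[str],
    hidden: int = DEFAULT_HIDDEN,
    split: float = DEFAULT_SPLIT,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    drug_pool: list[str] | None = None,
    max_iter: int = 2000,
    alpha: float = 0.1,
    solver: str = "lbfgs",
) -> DrugPredictionReport:
    """Repeated balanced MLP evaluation of drug–disease prediction.

    ``drug_pool`` restricts candidates (default: every id in the embedding).
    Each repeat draws a fresh equal-size negative sample from the non-positive
    drugs and a fresh train/test split; per-repeat test drugs are disjoint
    from training drugs by construction. The default solver is L-BFGS with
    moderate L2 regularization: positive sets number tens of drugs, and
    full-batch quasi-Newton training is the reliable regime for samples that
    small (stochastic optimizers need far more data per epoch to converge).
    """
    pool = list(drug_pool) if drug_pool is not None else list(emb.ids)
    pos = sorted(set(positives) & set(pool))
    if len(pos) < MIN_POSITIVES:
        raise ValueError(
            f"need at least {MIN_POSITIVES} positive drugs with embeddings, "
            f"got {len(pos)}")
    neg_pool = sorted(set(pool) - set(pos))
    if len(neg_pool) < len(pos):
        raise ValueError("negative pool smaller than positive set")

    index = {d: i for i, d in enumerate(emb.ids)}
    X_pos = emb.U[[index[d] for d in pos]]
    seeds = np.random.SeedSequence(seed).spawn(repeats)

    rocs: list[ROCCurve] = []
    prcs: list[PRCurve] = []
    aucs = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        neg = rng.choice(neg_pool, size=len(pos), replace=False)
        X = np.vstack([X_pos, emb.U[[index[d] for d in neg]]])
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(pos))])
        order = rng.permutation(len(y))
        n_train = int(round(split * len(y)))
        train, test = order[:n_train], order[n_train:]
        assert not set(train) & set(test)

        clf = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            solver=solver,
            alpha=alpha,
            max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(X[train], y[train])
        prob = clf.predict_proba(X[test])[:, 1]
        roc, prc = roc_prc(prob, y[test].astype(int))
        rocs.append(roc)
        prcs.append(prc)
        aucs.append(auc(roc))

    roc_grid, roc_mean, roc_sd = average_curves_roc(rocs)
    prc_grid, prc_mean, prc_sd = average_curves_prc(prcs)
    return DrugPredictionReport(
        aucs=np.asarray(aucs),
        roc_grid=roc_grid, roc_mean=roc_mean, roc_sd=roc_sd,
        prc_grid=prc_grid, prc_mean=prc_mean, prc_sd=prc_sd,
    )
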