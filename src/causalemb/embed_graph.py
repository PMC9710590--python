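"""Graph-based gene embeddings (E3).

Pipeline: (1) build a signed coregulation similarity graph H whose edge
z-scores measure how concordantly two regulators sign their shared targets,
(2) losslessly encode the signs by replicating every node into a u- and a
v-copy — positive edges wire the copies in parallel, negative edges
crosswise — giving an unsigned graph H', and (3) embed H' with random-walk
skip-gram (node2vec with p = q = 1 reduces to uniform first-order walks).
The u-replica vectors are the gene embeddings; anti-similar genes end up
near each other's opposite replica.

The z-score between regulators i and k is
    z_ik = (sum_j s_ij s_kj) / sqrt(N_ik),  N_ik = sum_j |s_ij| |s_kj|,
i.e. the sum of sign agreements over the N_ik shared targets, scaled so
that under a random-sign null (each product +-1 with equal probability) z
has unit variance. |z| >= z_cutoff (default 1.5) keeps an edge.

The skip-gram trainer (negative sampling) is implemented directly in numpy
with mini-batched updates; at gene-graph scale this trains in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .embed_spectral import EmbeddingMatrix, SignedAdjacency
from .knowledge_model import CausalGraph

logger = logging.getLogger(__name__)

DEFAULT_Z_CUTOFF = 1.5
DEFAULT_WALK_LENGTH = 30
DEFAULT_WALKS_PER_NODE = 100
DEFAULT_WINDOW = 10
DEFAULT_NEGATIVE = 5
DEFAULT_SG_EPOCHS = 5

U_SUFFIX = "::u"
V_SUFFIX = "::v"


@dataclass
class SimilarityGraph:
    """Signed coregulation graph H over regulator nodes.

    ``edges`` holds (i, k, sign, z) with i < k lexicographically; only pairs
    with |z| >= z_cutoff and at least one shared target are stored.
    """

    nodes: list[str]
    edges: list[tuple[str, str, int, float]]
    z_cutoff: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, k, sign, z in self.edges:
            g.add_edge(i, k, sign=sign, z=z)
        return g


def coregulation_graph(G: CausalGraph, z_cutoff: float = DEFAULT_Z_CUTOFF
                       ) -> SimilarityGraph:
    """Signed similarity graph H from shared-target sign concordance."""
    if z_cutoff <= 0:
        raise ValueError("z_cutoff must be positive")
    A = G.sign_matrix().astype(np.float64)
    agree = (A @ A.T).toarray()              # sum_j s_ij s_kj
    shared = (abs(A) @ abs(A).T).toarray()   # N_ik
    n = len(G.regulators)
    edges = []
    iu, ku = np.triu_indices(n, k=1)
    mask = shared[iu, ku] > 0
    for i, k in zip(iu[mask], ku[mask]):
        z = agree[i, k] / np.sqrt(shared[i, k])
        if abs(z) >= z_cutoff:
            edges.append((G.regulators[i], G.regulators[k],
                          1 if z > 0 else -1, float(z)))
    if not edges:
        logger.warning("similarity graph is empty at z_cutoff=%.3g", z_cutoff)
    return SimilarityGraph(list(G.regulators), edges, z_cutoff)


def replicate_unsigned(H: SimilarityGraph) -> nx.Graph:
    """Unsigned replicated graph H'.

    Every node i of H becomes two nodes i::u and i::v. A positive H-edge
    (i, k) becomes the parallel pair (i::u, k::u), (i::v, k::v); a negative
    edge the crosswise pair (i::u, k::v), (i::v, k::u). Collapsing the
    replicas recovers H's topology and signs exactly.
    """
    g = nx.Graph()
    for node in H.nodes:
        g.add_node(node + U_SUFFIX)
        g.add_node(node + V_SUFFIX)
    for i, k, sign, z in H.edges:
        if sign > 0:
            g.add_edge(i + U_SUFFIX, k + U_SUFFIX)
            g.add_edge(i + V_SUFFIX, k + V_SUFFIX)
        else:
            g.add_edge(i + U_SUFFIX, k + V_SUFFIX)
            g.add_edge(i + V_SUFFIX, k + U_SUFFIX)
    return g


def collapse_replicas(Hp: nx.Graph) -> SimilarityGraph:
    """Inverse of :func:`replicate_unsigned` (sign recovered from wiring;
    z-scores are not stored in H' and are returned as +-1)."""
    bases = sorted({n[:-len(U_SUFFIX)] for n in Hp.nodes})
    edges = {}
    for a, b in Hp.edges:
        base_a, rep_a = a[:-3], a[-3:]
        base_b, rep_b = b[:-3], b[-3:]
        i, k = sorted((base_a, base_b))
        sign = 1 if rep_a == rep_b else -1
        edges[(i, k)] = sign
    return SimilarityGraph(
        bases,
        [(i, k, s, float(s)) for (i, k), s in sorted(edges.items())],
        z_cutoff=0.0,
    )


def walk_corpus(
    Hp: nx.Graph,
    walk_length: int = DEFAULT_WALK_LENGTH,
    walks_per_node: int = DEFAULT_WALKS_PER_NODE,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> list[list[str]]:
    """node2vec-style second-order random walks over H'.

    Return-parameter p and in-out parameter q bias the second step onward;
    with p = q = 1 the walk is a uniform first-order random walk. Isolated
    nodes yield length-1 walks. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(Hp.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    neighbors = [sorted(Hp.neighbors(n)) for n in nodes]
    uniform = (p == 1.0 and q == 1.0)

    walks: list[list[str]] = []
    for _ in range(walks_per_node):
        for start in nodes:
            walk = [start]
            if not neighbors[index[start]]:
                walks.append(walk)
                continue
            while len(walk) < walk_length:
                cur = walk[-1]
                nbrs = neighbors[index[cur]]
                if not nbrs:
                    break
                if uniform or len(walk) == 1:
                    nxt = nbrs[int(rng.integers(len(nbrs)))]
                else:
                    prev = walk[-2]
                    prev_nbrs = set(neighbors[index[prev]])
                    w = np.array([
                        1.0 / p if nb == prev
                        else (1.0 if nb in prev_nbrs else 1.0 / q)
                        for nb in nbrs
                    ])
                    w /= w.sum()
                    nxt = nbrs[int(rng.choice(len(nbrs), p=w))]
                walk.append(nxt)
            walks.append(walk)
    return walks


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def skipgram_embed(
    corpus: list[list[str]],
    K: int,
    window: int = DEFAULT_WINDOW,
    epochs: int = DEFAULT_SG_EPOCHS,
    seed: int = 0,
    negative: int = DEFAULT_NEGATIVE,
    learning_rate: float = 0.025,
    batch_size: int = 256,
) -> tuple[EmbeddingMatrix, np.ndarray, list[str]]:
    """Skip-gram with negative sampling over the walk corpus.

    Returns (u-replica embeddings keyed by gene id, v-replica matrix
    row-aligned with those ids, list of genes covered). Genes whose replicas
    never occur in the corpus next to another node (isolated in H') get no
    embedding and are excluded with a logged count.
    """
    vocab = sorted({n for walk in corpus for n in walk})
    v_index = {n: i for i, n in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(seed)

    centers_l, contexts_l = [], []
    counts = np.zeros(V, dtype=np.int64)
    for walk in corpus:
        idx = [v_index[n] for n in walk]
        for pos, c in enumerate(idx):
            counts[c] += 1
            lo = max(0, pos - window)
            hi = min(len(idx), pos + window + 1)
            for ctx_pos in range(lo, hi):
                if ctx_pos != pos:
                    centers_l.append(c)
                    contexts_l.append(idx[ctx_pos])
    centers = np.asarray(centers_l, dtype=np.int64)
    contexts = np.asarray(contexts_l, dtype=np.int64)
    n_pairs = centers.size
    if n_pairs == 0:
        raise ValueError("empty walk corpus: no co-occurring node pairs")

    # unigram^(3/4) negative-sampling distribution
    noise = counts.astype(float) ** 0.75
    noise /= noise.sum()

    Win = (rng.random((V, K)) - 0.5) / K
    Wout = np.zeros((V, K))

    total_batches = epochs * ((n_pairs + batch_size - 1) // batch_size)
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch_size):
            lr = learning_rate * max(
                1e-4 / learning_rate, 1.0 - batch_no / total_batches)
            batch_no += 1
            b = order[s:s + batch_size]
            c, o = centers[b], contexts[b]
            neg = rng.choice(V, size=(b.size, negative), p=noise)

            vc = Win[c]                      # B x K
            vo = Wout[o]                     # B x K
            vn = Wout[neg]                   # B x neg x K

            g_pos = (_sigmoid(np.sum(vc * vo, axis=1)) - 1.0)[:, None]
            g_neg = _sigmoid(np.einsum("bk,bnk->bn", vc, vn))[..., None]

            # accumulate per-row gradients and average over each row's
            # occurrences in the batch: a node repeated many times in one
            # batch takes one lr-sized step, not a summed (divergent) one
            grad_in = np.zeros_like(Win)
            np.add.at(grad_in, c, g_pos * vo
                      + np.einsum("bnj,bnk->bk", g_neg, vn))
            cnt_in = np.bincount(c, minlength=V)[:, None]
            Win -= lr * grad_in / np.maximum(cnt_in, 1)

            grad_out = np.zeros_like(Wout)
            np.add.at(grad_out, o, g_pos * vc)
            cnt_out = np.bincount(o, minlength=V)
            for slot in range(negative):
                np.add.at(grad_out, neg[:, slot], g_neg[:, slot] * vc)
                cnt_out = cnt_out + np.bincount(neg[:, slot], minlength=V)
            Wout -= lr * grad_out / np.maximum(cnt_out, 1)[:, None]

    genes = sorted({n[:-len(U_SUFFIX)] for n in vocab
                    if n.endswith(U_SUFFIX)})
    covered = [g for g in genes
               if g + U_SUFFIX in v_index and g + V_SUFFIX in v_index]
    U = np.vstack([Win[v_index[g + U_SUFFIX]] for g in covered])
    Vm = np.vstack([Win[v_index[g + V_SUFFIX]] for g in covered])
    return EmbeddingMatrix(covered, U, method="E3"), Vm, covered


def graph_embed(
    G: CausalGraph,
    K: int,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    walk_length: int = DEFAULT_WALK_LENGTH,
    walks_per_node: int = DEFAULT_WALKS_PER_NODE,
    window: int = DEFAULT_WINDOW,
    epochs: int = DEFAULT_SG_EPOCHS,
    seed: int = 0,
) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Full E3 pipeline: similarity graph -> replication -> walks ->
    skip-gram. Genes isolated in H get no embedding (logged)."""
    H = coregulation_graph(G, z_cutoff)
    connected = {n for e in H.edges for n in (e[0], e[1])}
    n_isolated = len(H.nodes) - len(connected)
    if n_isolated:
        logger.info("%d genes isolated at z_cutoff=%.3g; excluded from E3",
                    n_isolated, z_cutoff)
    Hp = replicate_unsigned(
        SimilarityGraph(sorted(connected), H.edges, H.z_cutoff))
    corpus = walk_corpus(Hp, walk_length, walks_per_node, seed=seed)
    emb, Vm, _ = skipgram_embed(corpus, K, window=window, epochs=epochs,
                                seed=seed)
    return emb, Vm


# signed-adjacency convenience used by the CLI: E3 needs the raw graph, but
# callers holding a SignedAdjacency can recover signs from nonzeros
def adjacency_sign_graph(W: SignedAdjacency) -> CausalGraph:
    from .knowledge_model import SignedEdge

    coo = W.W.tocoo()
    edges = [
        SignedEdge(W.row_ids[i], W.col_ids[j], 1 if v > 0 else -1)
        for i, j, v in zip(coo.row, coo.col, coo.data)
    ]
    return CausalGraph(list(W.row_ids), list(W.col_ids), edges)
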