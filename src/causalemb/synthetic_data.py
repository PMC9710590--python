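"""Synthetic signed causal graphs with planted low-dimensional structure.

The generator emulates the statistical shape of a literature-curated causal
expression knowledge graph: a sparse signed bipartite regulator->target graph
whose rows share latent low-rank structure, a sparse signed gene–function
matrix driven by the same latent gene vectors, and an optional drug
extension. Every regulator i, target j and function f carries a latent
vector drawn i.i.d. standard normal in d dimensions; an emitted edge i->j
gets sign(g_i . t_j + b), where the scalar offset b is calibrated by
bisection so the positive:negative sign ratio matches the roughly 2:1
imbalance observed in curated expression content. Because the planted
structure is genuinely low-rank, downstream embedding methods recovering it
is a meaningful test of the whole pipeline, not just of plumbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .knowledge_model import (
    AssociationMatrix,
    CausalGraph,
    Entity,
    FunctionTerm,
    SignedEdge,
)

logger = logging.getLogger(__name__)

#: positive:negative sign ratio of curated expression edges
SIGN_RATIO = 2.0


@dataclass
class LatentModel:
    """Planted latent-factor model shared by all generator stages.

    Parameters
    ----------
    n_genes, n_targets, n_functions : int
        Numbers of regulator genes, expression-regulated targets, and
        function/disease terms.
    d : int
        Planted latent dimension.
    density : float
        Expected fraction of nonzero entries of the sign matrix.
    noise_rate : float
        Probability that an emitted sign is flipped; must be < 0.5 so the
        planted signal stays identifiable.
    seed : int
        Integer seed; all outputs are reproducible from it.
    """

    n_genes: int = 200
    n_targets: int = 1000
    n_functions: int = 100
    d: int = 10
    density: float = 0.05
    noise_rate: float = 0.0
    seed: int = 0

    gene_vectors: np.ndarray = field(init=False, repr=False)
    target_vectors: np.ndarray = field(init=False, repr=False)
    function_vectors: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        rng = np.random.default_rng(self.seed)
        self.gene_vectors = rng.standard_normal((self.n_genes, self.d))
        self.target_vectors = rng.standard_normal((self.n_targets, self.d))
        self.function_vectors = rng.standard_normal((self.n_functions, self.d))

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child generator for one generator stage."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        )


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _target_ids(n: int) -> list[str]:
    return [f"t{i:05d}" for i in range(n)]


def _function_ids(n: int) -> list[str]:
    return [f"f{i:05d}" for i in range(n)]


def _drug_ids(n: int) -> list[str]:
    return [f"d{i:05d}" for i in range(n)]


def calibrate_sign_offset(
    scores: np.ndarray, ratio: float = SIGN_RATIO, tol: float = 1e-6
) -> float:
    """Scalar offset b such that sign(scores + b) has the requested
    positive:negative ratio, found by bisection on the empirical CDF."""
    target_pos = ratio / (1.0 + ratio)
    lo, hi = -np.max(np.abs(scores)) - 1.0, np.max(np.abs(scores)) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac_pos = np.mean(scores + mid > 0)
        if frac_pos < target_pos:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def generate_expression_graph(
    model: LatentModel,
) -> tuple[CausalGraph, np.ndarray]:
    """Sparse signed bipartite expression graph with planted structure.

    Each (regulator i, target j) pair carries an edge with probability
    ``density``; the edge sign is sign(g_i . t_j + b) with b calibrated to
    the 2:1 positive:negative imbalance, then flipped with probability
    ``noise_rate``. Regulators that end up with no edge are dropped (their
    rows cannot be normalized) with a logged count.

    Returns the graph and the latent gene vectors of the *retained*
    regulators, row-aligned with ``graph.regulators``.
    """
    rng = model.rng(0)
    genes = _gene_ids(model.n_genes)
    targets = _target_ids(model.n_targets)

    mask = rng.random((model.n_genes, model.n_targets)) < model.density
    raw = model.gene_vectors @ model.target_vectors.T
    b = calibrate_sign_offset(raw[mask])
    signs = np.where(raw + b > 0, 1, -1).astype(np.int8)
    if model.noise_rate > 0:
        flips = rng.random((model.n_genes, model.n_targets)) < model.noise_rate
        signs = np.where(flips, -signs, signs)

    edges = [
        SignedEdge(genes[i], targets[j], int(signs[i, j]))
        for i, j in zip(*np.nonzero(mask))
    ]
    kept_rows = sorted({g for g in (e.source for e in edges)})
    dropped = len(genes) - len(kept_rows)
    if dropped:
        logger.info("dropped %d regulators with no targets", dropped)
    kept_targets = sorted({e.target for e in edges})
    graph = CausalGraph(
        kept_rows, kept_targets, edges,
        {g: Entity(g, kind="gene") for g in kept_rows},
    )
    keep_idx = [int(g[1:]) for g in kept_rows]
    return graph, model.gene_vectors[keep_idx]


def generate_function_associations(
    model: LatentModel, genes_per_function: int = 20,
    genes: list[str] | None = None,
) -> AssociationMatrix:
    """Signed gene–function matrix planted in the same latent space.

    For each function j, the ``genes_per_function`` genes with the largest
    |g_i . f_j| receive Y_ij = sign(g_i . f_j), flipped with probability
    ``noise_rate``. Every column therefore has exactly
    ``genes_per_function`` nonzeros (before any downstream masking).
    """
    rng = model.rng(1)
    gene_list = genes if genes is not None else _gene_ids(model.n_genes)
    idx = [int(g[1:]) for g in gene_list]
    G = model.gene_vectors[idx]
    functions = _function_ids(model.n_functions)

    raw = G @ model.function_vectors.T  # n_genes x n_functions
    rows, cols, data = [], [], []
    for j in range(model.n_functions):
        top = np.argsort(-np.abs(raw[:, j]), kind="stable")[:genes_per_function]
        for i in top:
            s = 1 if raw[i, j] > 0 else -1
            if model.noise_rate > 0 and rng.random() < model.noise_rate:
                s = -s
            rows.append(i)
            cols.append(j)
            data.append(s)
    mat = sparse.csr_matrix(
        (data, (rows, cols)),
        shape=(len(gene_list), model.n_functions), dtype=np.int8,
    )
    terms = {f: FunctionTerm(f) for f in functions}
    return AssociationMatrix(list(gene_list), functions, mat, terms)


def planted_function_signs(
    model: LatentModel, genes: list[str]
) -> np.ndarray:
    """Ground-truth sign(g_i . f_j) matrix for the supplied genes — the
    planted causal directions before top-k truncation and noise."""
    idx = [int(g[1:]) for g in genes]
    raw = model.gene_vectors[idx] @ model.function_vectors.T
    return np.sign(raw).astype(np.int8)


def generate_drug_extension(
    model: LatentModel, n_drugs: int = 100, n_diseases: int = 5,
    label_quantile: float = 0.8, effect_size: float = 1.0,
) -> tuple[list[SignedEdge], dict[str, list[str]], np.ndarray]:
    """Drug rows for the expression graph plus planted drug–disease labels.

    Drugs get fresh latent vectors and emit signed expression edges exactly
    as genes do (same density, offset and noise). The first ``n_diseases``
    function terms double as diseases: a drug is labeled positive for
    disease j iff drug_vector . f_j exceeds the ``label_quantile`` quantile
    of the drug-score distribution for that disease (a planted activation
    threshold). Drugs passing the threshold additionally receive a shared
    mechanism component ``effect_size`` . f_j/|f_j| on their latent vector
    — drugs indicated for the same disease act along a common axis, the
    coherence that makes approved-drug sets more predictable than arbitrary
    ones. The shift is monotone in the disease score, so the threshold
    labeling is unchanged by it.

    Returns (drug expression edges, {disease id: positive drug ids},
    drug latent vectors).
    """
    rng = model.rng(2)
    drugs = _drug_ids(n_drugs)
    targets = _target_ids(model.n_targets)
    drug_vectors = rng.standard_normal((n_drugs, model.d))

    diseases = _function_ids(model.n_functions)[:n_diseases]
    disease_vecs = model.function_vectors[:n_diseases]
    base_scores = drug_vectors @ disease_vecs.T
    for j in range(n_diseases):
        cut = np.quantile(base_scores[:, j], label_quantile)
        aligned = base_scores[:, j] > cut
        f = disease_vecs[j]
        drug_vectors[aligned] += effect_size * f / np.linalg.norm(f)

    mask = rng.random((n_drugs, model.n_targets)) < model.density
    raw = drug_vectors @ model.target_vectors.T
    b = calibrate_sign_offset(raw[mask]) if mask.any() else 0.0
    signs = np.where(raw + b > 0, 1, -1).astype(np.int8)
    if model.noise_rate > 0:
        flips = rng.random((n_drugs, model.n_targets)) < model.noise_rate
        signs = np.where(flips, -signs, signs)
    edges = [
        SignedEdge(drugs[i], targets[j], int(signs[i, j]))
        for i, j in zip(*np.nonzero(mask))
    ]

    scores = drug_vectors @ disease_vecs.T  # n_drugs x n_diseases
    positives: dict[str, list[str]] = {}
    for j, dis in enumerate(diseases):
        cut = np.quantile(scores[:, j], label_quantile)
        positives[dis] = [drugs[i] for i in range(n_drugs)
                          if scores[i, j] > cut]
    return edges, positives, drug_vectors
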