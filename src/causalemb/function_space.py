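"""Function and disease embeddings, gene–function scoring, and latent
relationship analyses.

Function embedding vectors live in the same K-dimensional space as gene
embeddings. For each function j with signed gene-association column y_j, the
vector p_j minimizes the least-squares objective sum_i (x_i . p_j - Y_ij)^2,
i.e. p_j = (U^T U)^{-1} U^T y_j; when the gene embedding U is orthonormal
(spectral method) this reduces to p_j = U^T y_j. Vectors are normalized to
unit length (p~_j) so that the score distribution of isotropic random gene
embeddings is identical across functions.

The gene–function score is the scalar product s_ij = p~_j . x_i: positive
scores predict activation, negative inhibition, and |s_ij| ranks how
strongly gene i is tied to the consensus gene sets of function j. Scores
are also expressed as z-scores against an isotropic-random-function null:
a random unit vector p~ in K dimensions gives s with standard deviation
|x_i| / sqrt(K), so z_ij = s_ij sqrt(K) / |x_i|.

Function–function relations use cosine similarity, which for normalized
vectors is the plain dot product; the 2-sigma significance threshold for K
dimensions is 2 / sqrt(K) (the component of a random unit vector has
variance 1/K).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .embed_spectral import EmbeddingMatrix
from .knowledge_model import AssociationMatrix

logger = logging.getLogger(__name__)

ORTHONORMAL_ATOL = 1e-10


@dataclass
class FunctionEmbeddings:
    """Function embedding vectors: raw rows P and unit-normalized P_norm.

    Functions whose regression produced an all-zero vector (no associated
    genes in the embedding, or y_j = 0) are flagged in ``degenerate`` and
    carry zero rows in P_norm; they are excluded from scoring output.
    """

    functions: list[str]
    P: np.ndarray          # J x K
    P_norm: np.ndarray     # J x K, unit rows (zero rows for degenerate)
    degenerate: np.ndarray  # bool mask, J

    def vector(self, function_id: str) -> np.ndarray:
        return self.P_norm[self.functions.index(function_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P_norm,
                          columns=[f"e{k}" for k in range(self.P.shape[1])])
        df.insert(0, "id", self.functions)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g")


@dataclass
class ScoreMatrix:
    """Gene–function scores s_ij = p~_j . x_i and their z-scores."""

    genes: list[str]
    functions: list[str]
    scores: np.ndarray             # N x J
    zscores: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        coo = []
        for j, f in enumerate(self.functions):
            for i, g in enumerate(self.genes):
                row = [g, f, self.scores[i, j]]
                if self.zscores is not None:
                    row.append(self.zscores[i, j])
                coo.append(row)
        cols = ["gene", "function", "score"] + (
            ["zscore"] if self.zscores is not None else [])
        return pd.DataFrame(coo, columns=cols)


def fit_function_embeddings(
    U: EmbeddingMatrix, Y: AssociationMatrix
) -> FunctionEmbeddings:
    """Per-function least-squares fit p_j = (U^T U)^{-1} U^T y_j.

    Uses the orthonormal shortcut U^T y_j when U^T U = I (spectral
    embeddings); otherwise solves the normal equations once for all
    functions. Raises if U^T U is numerically singular (embedding dimension
    too large for the number of genes).
    """
    if U.ids != list(Y.genes):
        raise ValueError("embedding rows and association rows are not aligned")
    X = U.U
    K = X.shape[1]
    Ymat = sparse.csr_matrix(Y.matrix, dtype=float)

    gram = X.T @ X
    if np.allclose(gram, np.eye(K), atol=ORTHONORMAL_ATOL):
        P = (X.T @ Ymat).T  # J x K; equals the general solution exactly
    else:
        cond = np.linalg.cond(gram)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"U^T U is ill-conditioned (cond={cond:.2e}); "
                "reduce the embedding dimension K"
            )
        P = np.linalg.solve(gram, X.T @ Ymat.toarray()).T

    P = np.asarray(P)
    norms = np.linalg.norm(P, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        logger.info("%d functions have zero embedding vectors (no usable "
                    "gene associations)", int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, norms)
    P_norm = P / safe[:, None]
    P_norm[degenerate] = 0.0
    return FunctionEmbeddings(list(Y.functions), P, P_norm, degenerate)


def score_genes(U: EmbeddingMatrix, F: FunctionEmbeddings) -> ScoreMatrix:
    """s_ij = p~_j . x_i. Exactly antisymmetric under negation of either a
    gene vector or a function vector."""
    S = U.U @ F.P_norm.T
    return ScoreMatrix(list(U.ids), list(F.functions), S)


def score_zscores(S: ScoreMatrix, U: EmbeddingMatrix,
                  empirical: bool = False) -> ScoreMatrix:
    """Fill in z-scores.

    Analytic null (default): a random unit function vector gives gene i a
    score with standard deviation |x_i| / sqrt(K), hence
    z_ij = s_ij sqrt(K) / |x_i|. With ``empirical=True``, scores are instead
    standardized per function column (mean 0, SD 1 over genes).
    """
    if empirical:
        mu = S.scores.mean(axis=0, keepdims=True)
        sd = S.scores.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (S.scores - mu) / sd
    else:
        K = U.U.shape[1]
        norms = np.linalg.norm(U.U, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        Z = S.scores * np.sqrt(K) / safe[:, None]
    return ScoreMatrix(S.genes, S.functions, S.scores, Z)


def cosine_similarity(a: str, b: str, F: FunctionEmbeddings) -> float:
    """Cosine similarity of two functions — the dot product of their
    normalized embedding vectors; negative values mean anti-similarity."""
    return float(F.vector(a) @ F.vector(b))


def similarity_threshold(K: int) -> float:
    """Two-sigma significance threshold for cosine similarity in K
    dimensions: 2 K^(-1/2). A component of a random unit vector has variance
    1/K (from sum_i <x_i^2> = 1 with K equivalent components)."""
    if K < 1:
        raise ValueError("K must be positive")
    return 2.0 / np.sqrt(K)


# ---------------------------------------------------------------------------
# Latent-relationship analyses
# ---------------------------------------------------------------------------

def project_process_pairs(
    F: FunctionEmbeddings,
    pairs: list[tuple[str, str]],
) -> tuple[np.ndarray, list[str]]:
    """Project the functions appearing in ``pairs`` onto their top-2
    principal components (mean-centered, no variance scaling).

    Returns (coords, ids): a (n_functions x 2) array and the function ids in
    row order. If the paired functions differ only by a shared additive
    process offset, the segments joining each pair are parallel in this
    plane.
    """
    ids = sorted({f for pair in pairs for f in pair})
    X = np.vstack([F.vector(f) for f in ids])
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, ids


def angle_parallelism_test(
    coords: np.ndarray,
    ids: list[str],
    pairs: list[tuple[str, str]],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for parallelism of pair segments in the 2-D plane.

    The statistic is the spread of the angles the segments form with the
    horizontal axis, taken modulo pi (segments are undirected). Angle spread
    is measured circularly on doubled angles so that near-parallel segments
    straddling the 0/pi wrap-around are not penalized; it is exactly 0 when
    all segments are parallel. The null shuffles the b-endpoints among the
    pairs (pure permutation, no replacement), and
    p = (1 + #{shuffled SD <= observed SD}) / (1 + n_permutations).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    index = {f: i for i, f in enumerate(ids)}
    a_pts = np.array([coords[index[a]] for a, _ in pairs], dtype=float)
    b_pts = np.array([coords[index[b]] for _, b in pairs], dtype=float)

    keep = ~np.all(np.isclose(a_pts, b_pts), axis=1)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} pairs with coincident "
                      "endpoints", RuntimeWarning)
        a_pts, b_pts = a_pts[keep], b_pts[keep]
    if len(a_pts) < 3:
        raise ValueError("fewer than 3 non-degenerate pairs remain")

    def angle_sd(bp: np.ndarray) -> float:
        d = bp - a_pts
        theta = np.arctan2(d[:, 1], d[:, 0])  # angles; doubling folds mod pi
        R = np.abs(np.mean(np.exp(2j * theta)))
        R = min(R, 1.0)
        return float(np.sqrt(max(-np.log(R), 0.0)) / 2.0)

    observed = angle_sd(b_pts)
    rng = np.random.default_rng(seed)
    hits = 0
    n = len(a_pts)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if angle_sd(b_pts[perm]) <= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return observed, p


def disease_map_coordinates(
    F: FunctionEmbeddings,
    disease_ids: list[str],
    n_pca: int = 20,
    seed: int = 0,
    perplexity: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disease map: exact PCA to ``n_pca`` dimensions, then a seeded 2-D
    t-SNE layout. The PCA stage is deterministic and testable; the layout is
    stochastic but reproducible from the seed.

    Returns (pca_coords: n x n_pca, map_coords: n x 2).
    """
    X = np.vstack([F.vector(d) for d in disease_ids])
    n = X.shape[0]
    n_comp = min(n_pca, n, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    reduced = pca.fit_transform(X)
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    layout = tsne.fit_transform(reduced)
    return reduced, layout
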