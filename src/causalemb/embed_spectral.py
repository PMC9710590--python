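"""Spectral gene embeddings (E1) from the signed bi-adjacency matrix.

The signed weighted matrix W has entries W_ij = s_ij / sqrt(N_i), where s_ij
is the edge sign and N_i the number of targets regulated by regulator i.
The square-root normalization makes every row of W a unit vector, so the
gene–gene similarity S = W W^T has unit diagonal and entries in [-1, 1]:
S_ik is the signed cosine overlap of the downstream regulation patterns of
regulators i and k (identical patterns give +1, exactly opposite ones -1).

The spectral embedding is the truncated SVD W ~ U Sigma V^T; the rows of the
N x K matrix U are the embedding vectors, the columns of U are eigenvectors
of S to its top-K eigenvalues, and U^T U = I.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import svds

from .knowledge_model import CausalGraph

logger = logging.getLogger(__name__)

#: below this many cells, use the exact dense SVD; above, sparse iterative
DENSE_SVD_MAX_CELLS = 1_000_000
#: convergence tolerance of the iterative solver
SVD_TOL = 1e-10


@dataclass
class SignedAdjacency:
    """Row-normalized signed bi-adjacency matrix W (sparse, N x M)."""

    W: sparse.csr_matrix
    row_ids: list[str]
    col_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape


@dataclass
class EmbeddingMatrix:
    """Entity embedding vectors as rows of U (N x K).

    For the spectral method, sigma holds the singular values (nonincreasing)
    and V the right factors, so U @ diag(sigma) @ V.T is the best rank-K
    approximation of W. Other methods fill sigma with ones and leave V None.
    """

    ids: list[str]
    U: np.ndarray
    method: str = "E1"
    sigma: np.ndarray | None = None
    V: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.U.shape[1]

    def vector(self, entity_id: str) -> np.ndarray:
        return self.U[self.ids.index(entity_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.U, columns=[f"e{k}" for k in range(self.K)])
        df.insert(0, "id", self.ids)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path, method: str = "E1") -> "EmbeddingMatrix":
        df = pd.read_csv(path, sep="\t")
        ids = df["id"].astype(str).tolist()
        U = df.drop(columns=["id"]).to_numpy(dtype=float)
        return cls(ids, U, method=method)


def build_weight_matrix(G: CausalGraph) -> SignedAdjacency:
    """W_ij = s_ij / sqrt(N_i); every row has unit norm so diag(W W^T) = 1."""
    S = G.sign_matrix().astype(float)
    degrees = G.out_degrees()
    if np.any(degrees == 0):
        bad = [G.regulators[i] for i in np.nonzero(degrees == 0)[0]]
        raise ValueError(
            f"regulators without edges must be filtered upstream: {bad[:5]}"
        )
    inv = sparse.diags(1.0 / np.sqrt(degrees))
    return SignedAdjacency(
        sparse.csr_matrix(inv @ S), list(G.regulators), list(G.targets)
    )


def similarity_matrix(W: SignedAdjacency) -> np.ndarray:
    """Signed gene–gene similarity S = W W^T (dense, symmetric, unit
    diagonal, entries in [-1, 1])."""
    S = (W.W @ W.W.T).toarray()
    return S


def _orient_columns(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: each column of U oriented so its
    largest-magnitude entry is positive. Scores are invariant to this; it
    only makes serialized embeddings reproducible."""
    for k in range(U.shape[1]):
        col = U[:, k]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            U[:, k] = -col
            V[:, k] = -V[:, k]
    return U, V


def spectral_embed(W: SignedAdjacency, K: int) -> EmbeddingMatrix:
    """Truncated SVD embedding: rows of U are the gene embedding vectors.

    Uses an exact dense SVD for small instances and a sparse iterative
    solver for large ones. If K exceeds the rank of W the trailing singular
    values are zero and a warning is emitted; U stays orthonormal either way.
    """
    N, M = W.shape
    if not (1 <= K <= min(N, M)):
        raise ValueError(f"K must be in [1, min(N, M)] = [1, {min(N, M)}]")

    if N * M <= DENSE_SVD_MAX_CELLS:
        U, s, Vt = np.linalg.svd(W.W.toarray(), full_matrices=False)
        U, s, V = U[:, :K], s[:K], Vt[:K].T
    else:
        if K >= min(N, M) - 1:  # svds requires K < min(N, M)
            U, s, Vt = np.linalg.svd(W.W.toarray(), full_matrices=False)
            U, s, V = U[:, :K], s[:K], Vt[:K].T
        else:
            U, s, Vt = svds(W.W, k=K, tol=SVD_TOL, random_state=0)
            order = np.argsort(-s)
            U, s, V = U[:, order], s[order], Vt[order].T

    rank_tol = max(N, M) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    n_zero = int(np.sum(s <= rank_tol))
    if n_zero:
        warnings.warn(
            f"requested K={K} exceeds numerical rank; "
            f"{n_zero} trailing singular values are zero",
            RuntimeWarning,
        )
    U, V = _orient_columns(U.copy(), V.copy())
    return EmbeddingMatrix(list(W.row_ids), U, method="E1", sigma=s, V=V)
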