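"""Neural-network gene embeddings (E2).

E2 extends the linear bottleneck behind the spectral method with one extra
nonlinear layer: one-hot input (N) -> linear, no bias -> embedding (K) ->
linear with bias + ReLU -> hidden (default 1000) -> linear, no bias ->
output (M), trained with MSE loss against the rows of the signed weighted
matrix W. The embedding vectors are the rows of the first layer's weight
matrix. Because neither the input layer nor the final layer carries a bias,
negating an embedding vector exactly negates the bias-free linear part of
the reconstruction — the sign symmetry that makes signed scores meaningful.

The trainer is a small full-batch gradient-descent loop with
adaptive-moment (Adam) updates written directly in numpy; at the scale of
curated causal graphs the full batch is a handful of dense matrix products
per epoch, so no GPU framework is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .embed_spectral import EmbeddingMatrix, SignedAdjacency

logger = logging.getLogger(__name__)

DEFAULT_HIDDEN = 1000
DEFAULT_LEARNING_RATE = 1e-3
PLATEAU_EPOCHS = 50
PLATEAU_REL_TOL = 1e-7


@dataclass
class NeuralEmbeddingResult:
    """Trained E2 network: embedding rows plus the reconstruction path."""

    embedding: EmbeddingMatrix
    W1: np.ndarray  # K x hidden
    b1: np.ndarray  # hidden
    W2: np.ndarray  # hidden x M
    loss_history: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]

    def decode(self, X: np.ndarray, relu: bool = True,
               include_bias: bool = True) -> np.ndarray:
        """Reconstruction of W rows from embedding vectors X (n x K).

        With ``relu=False, include_bias=False`` this is the bias-free linear
        sub-network, which is exactly antisymmetric: decode(-x) = -decode(x).
        """
        A = X @ self.W1
        if include_bias:
            A = A + self.b1
        if relu:
            A = np.maximum(A, 0.0)
        return A @ self.W2


def train_neural_embedding(
    W: SignedAdjacency,
    K: int,
    hidden: int = DEFAULT_HIDDEN,
    epochs: int = 2000,
    seed: int = 0,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    plateau_epochs: int = PLATEAU_EPOCHS,
) -> NeuralEmbeddingResult:
    """Train the E2 reconstruction network and return its embedding layer.

    Full-batch MSE against the dense rows of W; Adam updates; early stop
    when the loss has not improved by a relative ``PLATEAU_REL_TOL`` over
    ``plateau_epochs`` consecutive epochs. Fully reproducible from ``seed``.
    """
    target = W.W.toarray()
    N, M = target.shape
    rng = np.random.default_rng(seed)

    # He/Xavier-style scaled Gaussian initialization
    E = rng.standard_normal((N, K)) / np.sqrt(N)
    W1 = rng.standard_normal((K, hidden)) * np.sqrt(2.0 / K)
    b1 = np.zeros(hidden)
    W2 = rng.standard_normal((hidden, M)) / np.sqrt(hidden)

    params = [E, W1, b1, W2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    loss_history: list[float] = []
    best = np.inf
    best_epoch = 0
    for epoch in range(1, epochs + 1):
        pre = params[0] @ params[1] + params[2]
        act = np.maximum(pre, 0.0)
        out = act @ params[3]
        resid = out - target
        loss = float(np.mean(resid**2))
        loss_history.append(loss)

        d_out = (2.0 / (N * M)) * resid
        g3 = act.T @ d_out
        d_act = d_out @ params[3].T
        d_pre = d_act * (pre > 0)
        g1 = params[0].T @ d_pre
        g2 = d_pre.sum(axis=0)
        g0 = d_pre @ params[1].T

        for p, g, mi, vi in zip(params, (g0, g1, g2, g3), m, v):
            mi *= beta1
            mi += (1 - beta1) * g
            vi *= beta2
            vi += (1 - beta2) * g * g
            mhat = mi / (1 - beta1**epoch)
            vhat = vi / (1 - beta2**epoch)
            p -= learning_rate * mhat / (np.sqrt(vhat) + eps)

        if loss < best * (1 - PLATEAU_REL_TOL):
            best = loss
            best_epoch = epoch
        elif epoch - best_epoch >= plateau_epochs:
            logger.info("E2 training stopped at epoch %d (loss plateau)", epoch)
            break

    if len(loss_history) > 1 and loss_history[-1] >= loss_history[0]:
        logger.warning(
            "E2 training loss did not decrease (start %.3e, end %.3e); "
            "check learning rate %.1e and epochs %d",
            loss_history[0], loss_history[-1], learning_rate, epochs,
        )

    emb = EmbeddingMatrix(list(W.row_ids), params[0].copy(), method="E2")
    return NeuralEmbeddingResult(
        embedding=emb, W1=params[1], b1=params[2], W2=params[3],
        loss_history=loss_history,
    )
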