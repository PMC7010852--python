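"""Diffusion component analysis (DCA): low-dimensional node embeddings.

Diffusion states are high-dimensional and noisy; DCA compresses them into a
``d``-dimensional *node feature* x_i and *context feature* w_j per node such
that the inner product x_i·w_j models how often walks from i end at j.  The
original formulation fits a softmax model by KL-divergence minimization; the
variant implemented here drops the softmax normalizer, log-transforms the
diffusion matrix, and takes a truncated SVD — orders of magnitude faster and
near-indistinguishable in quality.  The KL objective is kept as a diagnostic
for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .graph_diffusion import DiffusionStateMatrix

__all__ = [
    "LogDiffusionMatrix",
    "EmbeddingPair",
    "log_transform",
    "svd_embed",
    "kl_objective",
]


@dataclass
class LogDiffusionMatrix:
    """Elementwise ``log(S + Q) − log(Q)`` of a diffusion matrix.

    ``Q`` is the constant pseudo-count matrix guarding against log(0);
    its canonical value is 1/n with n the number of walk sources (rows).
    Entries are nonnegative, and exactly 0 wherever S is 0.
    """

    values: np.ndarray
    pseudo_count: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log diffusion matrix contains non-finite entries")


@dataclass
class EmbeddingPair:
    """Node features X and context features W from a truncated SVD.

    ``X = U_d Σ_d^{1/2}`` and ``W = V_d Σ_d^{1/2}``, so ``X Wᵀ`` is the best
    rank-d Frobenius approximation of the factorized matrix.
    """

    node_features: np.ndarray
    context_features: np.ndarray
    singular_values: np.ndarray

    def __post_init__(self) -> None:
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be sorted non-increasing")

    @property
    def d(self) -> int:
        return self.node_features.shape[1]


def log_transform(
    S: DiffusionStateMatrix | np.ndarray, pseudo_count: float | None = None
) -> LogDiffusionMatrix:
    """Log-transform a (possibly fused, rectangular) diffusion matrix.

    ``L = log(S + Q) − log(Q)`` with constant ``Q = pseudo_count``; the
    default pseudo-count is 1/n where n is the number of rows.
    """
    values = S.states if isinstance(S, DiffusionStateMatrix) else np.asarray(S, float)
    if np.any(values < 0):
        raise ValueError("diffusion states must be nonnegative")
    if pseudo_count is None:
        pseudo_count = 1.0 / values.shape[0]
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    L = np.log(values + pseudo_count) - np.log(pseudo_count)
    return LogDiffusionMatrix(L, pseudo_count)


def svd_embed(L: LogDiffusionMatrix | np.ndarray, d: int) -> EmbeddingPair:
    """Rank-d truncated SVD embedding of the log diffusion matrix.

    Singular vector signs are fixed by forcing the largest-magnitude entry of
    each left singular vector positive, making the output deterministic
    across platforms.
    """
    M = L.values if isinstance(L, LogDiffusionMatrix) else np.asarray(L, float)
    n, m = M.shape
    if not 1 <= d <= min(n, m):
        raise ValueError(f"d must lie in [1, {min(n, m)}], got {d}")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    U, s, Vt = U[:, :d], s[:d], Vt[:d]
    # deterministic sign convention
    for i in range(d):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i] = -Vt[i]
    root = np.sqrt(s)
    return EmbeddingPair(U * root, Vt.T * root, s)


def kl_objective(
    S: DiffusionStateMatrix | np.ndarray, emb: EmbeddingPair
) -> float:
    """Mean KL divergence between diffusion states and the softmax model.

    ``C = (1/n) Σ_i D_KL(s_i ‖ ŝ_i)`` with ``ŝ_ij = softmax_j(x_i·w_j)``.
    A diagnostic of embedding quality on small instances; it is never
    optimized directly here.
    """
    P = S.states if isinstance(S, DiffusionStateMatrix) else np.asarray(S, float)
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of S must be probability distributions")
    logits = emb.node_features @ emb.context_features.T
    if logits.shape != P.shape:
        raise ValueError(
            f"embedding models a {logits.shape} matrix but S is {P.shape}"
        )
    log_shat = logits - logsumexp(logits, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * (np.log(P) - log_shat), 0.0)
    return float(terms.sum() / P.shape[0])
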