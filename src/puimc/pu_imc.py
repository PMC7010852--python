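"""PU-biased inductive matrix completion (the learning core).

The sparse binary gene–disease matrix P is modeled bilinearly from side
features: ``score(i, j) = x_iᵀ G Hᵀ y_j`` with low-rank factors G (f_g×k)
and H (f_d×k).  Known associations Ω+ carry full weight; every unknown cell
Ω− enters the squared loss as a negative example down-weighted by α < 1 —
the positive–unlabeled (PU) bias reflecting the prior that most unknown
pairs are truly unrelated.  The Frobenius penalty ½λ(‖G‖²+‖H‖²) is the
factored surrogate of the trace norm of Z = G Hᵀ.

Fitting alternates *exact* solves of the two convex subproblems (fix H,
solve G; fix G, solve H).  The dense weight structure (α everywhere plus a
sparse positive correction) lets each subproblem's normal matrix be built as
``α·(FᵀF ⊗ EᵀE)`` plus |Ω+| rank-one corrections, so the full complement Ω−
is used without ever materializing the N_g×N_d weight matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .evaluation import RankedPredictions

__all__ = [
    "AssociationMatrix",
    "SideFeatures",
    "PUIMCConfig",
    "FactorPair",
    "score",
    "pu_objective",
    "fit_puimc",
    "predict_rankings",
]


@dataclass
class AssociationMatrix:
    """Sparse binary gene×disease association matrix.

    Only the observed positives Ω+ are stored; every other cell is implicitly
    in the unknown set Ω−.  Optional string identifiers keep on-disk artifacts
    index-free.
    """

    shape: tuple[int, int]
    positives: set[tuple[int, int]]
    gene_ids: list[str] | None = None
    disease_ids: list[str] | None = None

    def __post_init__(self) -> None:
        n_g, n_d = self.shape
        self.positives = {(int(g), int(d)) for g, d in self.positives}
        for g, d in self.positives:
            if not (0 <= g < n_g and 0 <= d < n_d):
                raise ValueError(f"positive ({g}, {d}) outside shape {self.shape}")
        if self.gene_ids is not None and len(self.gene_ids) != n_g:
            raise ValueError("gene_ids length does not match shape")
        if self.disease_ids is not None and len(self.disease_ids) != n_d:
            raise ValueError("disease_ids length does not match shape")

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    def positive_array(self) -> np.ndarray:
        """Positives as a sorted (m, 2) integer array (deterministic order)."""
        if not self.positives:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.positives), dtype=int)

    def dense(self) -> np.ndarray:
        P = np.zeros(self.shape)
        pos = self.positive_array()
        if len(pos):
            P[pos[:, 0], pos[:, 1]] = 1.0
        return P

    def without(self, pairs) -> "AssociationMatrix":
        """Copy with the given pairs hidden (removed from Ω+)."""
        drop = {(int(g), int(d)) for g, d in pairs}
        return AssociationMatrix(
            self.shape, self.positives - drop, self.gene_ids, self.disease_ids
        )


@dataclass
class SideFeatures:
    """Gene (N_g×f_g) and disease (N_d×f_d) feature matrices."""

    gene_features: np.ndarray
    disease_features: np.ndarray

    def __post_init__(self) -> None:
        self.gene_features = np.asarray(self.gene_features, dtype=float)
        self.disease_features = np.asarray(self.disease_features, dtype=float)
        for name, M in (
            ("gene_features", self.gene_features),
            ("disease_features", self.disease_features),
        ):
            if M.ndim != 2 or not np.all(np.isfinite(M)):
                raise ValueError(f"{name} must be a finite 2-D matrix")


@dataclass
class PUIMCConfig:
    """Hyperparameters of the PU-biased completion.

    Defaults follow the settings used for the full-scale gene–disease
    problem: rank k=200, regularization λ=0.02, PU weight α=0.0035.  α must
    stay below 1 — known associations must outweigh unknown cells.
    """

    k: int = 200
    reg: float = 0.02
    alpha: float = 0.0035
    max_sweeps: int = 50
    objective_rel_tol: float = 1e-5
    seed: int = 0
    init_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("rank k must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1): unknown cells must weigh "
                             "less than known associations")
        if self.reg <= 0 or self.max_sweeps < 1 or self.objective_rel_tol <= 0:
            raise ValueError("invalid solver hyperparameters")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")


@dataclass
class FactorPair:
    """Learned bilinear factors; Z = G·Hᵀ maps gene features to disease features."""

    G: np.ndarray
    H: np.ndarray
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.G.shape[1] != self.H.shape[1]:
            raise ValueError("G and H must share the rank dimension")


def score(
    gene_feature: np.ndarray, disease_feature: np.ndarray, factors: FactorPair
) -> float:
    """Association score ``x_iᵀ·G·Hᵀ·y_j`` for one gene–disease pair."""
    x = np.asarray(gene_feature, dtype=float).ravel()
    y = np.asarray(disease_feature, dtype=float).ravel()
    if x.shape[0] != factors.G.shape[0]:
        raise ValueError(
            f"gene feature has {x.shape[0]} dims, G expects {factors.G.shape[0]}"
        )
    if y.shape[0] != factors.H.shape[0]:
        raise ValueError(
            f"disease feature has {y.shape[0]} dims, H expects {factors.H.shape[0]}"
        )
    return float((x @ factors.G) @ (factors.H.T @ y))


def _split_objective(
    Xg: np.ndarray,
    Yd: np.ndarray,
    G: np.ndarray,
    H: np.ndarray,
    pos: np.ndarray,
    alpha: float,
    reg: float,
) -> float:
    """Σ_{Ω+}(1−s)² + α·Σ_{Ω−}s² + (λ/2)(‖G‖²+‖H‖²) without touching Ω−.

    Uses α·Σ_all s² = α·tr((UᵀU)(VᵀV)) with U = Xg·G, V = Yd·H, then corrects
    the positive cells.
    """
    U = Xg @ G
    V = Yd @ H
    total_sq = float(np.einsum("ij,ij->", U.T @ U, V.T @ V))
    if len(pos):
        s_pos = np.einsum("ij,ij->i", U[pos[:, 0]], V[pos[:, 1]])
    else:
        s_pos = np.zeros(0)
    value = (
        alpha * total_sq
        + float(np.sum((1.0 - s_pos) ** 2))
        - alpha * float(np.sum(s_pos**2))
        + 0.5 * reg * (float(np.sum(G**2)) + float(np.sum(H**2)))
    )
    return value


def pu_objective(
    P: AssociationMatrix,
    feats: SideFeatures,
    factors: FactorPair,
    alpha: float,
    reg: float,
) -> float:
    """The PU-weighted squared-loss objective at the given factors."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if reg < 0:
        raise ValueError("reg must be nonnegative")
    return _split_objective(
        feats.gene_features,
        feats.disease_features,
        factors.G,
        factors.H,
        P.positive_array(),
        alpha,
        reg,
    )


def _solve_subproblem(
    F: np.ndarray,
    E: np.ndarray,
    pos_f: np.ndarray,
    pos_e: np.ndarray,
    alpha: float,
    reg: float,
) -> np.ndarray:
    """Exact minimizer M of  α·Σ_ij s² + Σ_pos[(1−s)² − α·s²] + (λ/2)‖M‖²
    with s = f_iᵀ·M·e_j, row features F, column-side embeddings E.

    Normal equations on m = vec(M) (row-major, so basis vectors are
    kron(f, e)):  [α·(FᵀF ⊗ EᵀE) + (1−α)·KᵀK + (λ/2)·I]·m = Σ_pos kron(f, e),
    with K the |Ω+|×(f·k) matrix of positive-cell Kronecker rows.
    """
    f_dim, k_dim = F.shape[1], E.shape[1]
    A = alpha * np.kron(F.T @ F, E.T @ E)
    if len(pos_f):
        K = np.einsum("pa,pb->pab", F[pos_f], E[pos_e]).reshape(len(pos_f), -1)
        A += (1.0 - alpha) * (K.T @ K)
        b = K.sum(axis=0)
    else:
        b = np.zeros(f_dim * k_dim)
    A[np.diag_indices_from(A)] += 0.5 * reg
    try:
        m = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular subproblem; raising the ridge floor", RuntimeWarning
        )
        A[np.diag_indices_from(A)] += max(reg, 1e-8)
        m = np.linalg.solve(A, b)
    return m.reshape(f_dim, k_dim)


def fit_puimc(
    P: AssociationMatrix, feats: SideFeatures, cfg: PUIMCConfig
) -> FactorPair:
    """Alternating exact minimization of the PU objective.

    Each half-sweep solves one convex regularized weighted least-squares
    subproblem exactly, so the recorded objective history is non-increasing.
    Stops when the relative objective decrease over a full sweep falls below
    ``objective_rel_tol``, or after ``max_sweeps`` sweeps.
    """
    Xg = feats.gene_features
    Yd = feats.disease_features
    if Xg.shape[0] != P.shape[0] or Yd.shape[0] != P.shape[1]:
        raise ValueError("feature row counts do not match the association matrix")
    if P.n_positives == 0:
        raise ValueError("training requires at least one known association")
    f_g, f_d = Xg.shape[1], Yd.shape[1]
    if cfg.k > min(f_g, f_d):
        raise ValueError(f"rank k={cfg.k} exceeds min(f_g, f_d)={min(f_g, f_d)}")

    rng = np.random.default_rng(cfg.seed)
    G = cfg.init_scale * rng.standard_normal((f_g, cfg.k))
    H = cfg.init_scale * rng.standard_normal((f_d, cfg.k))
    pos = P.positive_array()
    pos_g, pos_d = pos[:, 0], pos[:, 1]

    history = [_split_objective(Xg, Yd, G, H, pos, cfg.alpha, cfg.reg)]
    for _ in range(cfg.max_sweeps):
        V = Yd @ H
        G = _solve_subproblem(Xg, V, pos_g, pos_d, cfg.alpha, cfg.reg)
        history.append(_split_objective(Xg, Yd, G, H, pos, cfg.alpha, cfg.reg))
        U = Xg @ G
        H = _solve_subproblem(Yd, U, pos_d, pos_g, cfg.alpha, cfg.reg)
        history.append(_split_objective(Xg, Yd, G, H, pos, cfg.alpha, cfg.reg))
        prev, cur = history[-3], history[-1]
        if prev - cur < cfg.objective_rel_tol * max(abs(prev), 1e-12):
            break
    return FactorPair(G=G, H=H, objective_history=history)


def predict_rankings(
    factors: FactorPair,
    feats: SideFeatures,
    exclude: set[tuple[int, int]] | None = None,
) -> RankedPredictions:
    """Per-disease gene rankings by descending score.

    ``exclude`` removes (gene, disease) pairs — typically the training
    positives — from that disease's candidate list.  Ties are broken by
    ascending gene index, deterministically.
    """
    Xg = feats.gene_features
    Yd = feats.disease_features
    scores = (Xg @ factors.G) @ (Yd @ factors.H).T
    n_g, n_d = scores.shape
    excluded_by_d: dict[int, list[int]] = {}
    for g, d in exclude or ():
        excluded_by_d.setdefault(int(d), []).append(int(g))
    rankings: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for d in range(n_d):
        mask = np.ones(n_g, dtype=bool)
        if d in excluded_by_d:
            mask[excluded_by_d[d]] = False
        cand = np.flatnonzero(mask)
        sc = scores[cand, d]
        order = np.lexsort((cand, -sc))
        rankings[d] = (cand[order], sc[order])
    return RankedPredictions(rankings=rankings, n_genes=n_g)
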