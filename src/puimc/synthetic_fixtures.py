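"""Synthetic desk-scale inputs with the structure the method assumes.

Real gene–disease data (curated associations, interactome networks,
expression tables) cannot be redistributed, and at full scale would not fit
a test suite anyway.  This module generates structurally equivalent inputs:

* modular (planted-partition) similarity networks standing in for
  interactome / disease-similarity networks;
* correlated noisy feature tables from a low-rank factor model, standing in
  for expression and homolog-phenotype blocks;
* sparse bipartite positives planted from a random low-rank bilinear form on
  those features, with a held-back fraction as ground truth — the
  positive–unlabeled regime.

The planted generator draws from the same model family the completion step
fits.  That is deliberate and favorable: it validates the implementation
(can the pipeline recover plantable structure?), not any biological claim.

``parameter_recovery_experiment`` runs the entire pipeline — networks → RWR
→ DCA embedding, feature tables → denoising autoencoder, concatenation,
PU-IMC fit, ranking of held-out positives — and reports the evaluation
indices next to a random-scores baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dca_embedding import log_transform, svd_embed
from .denoising_autoencoder import DAEConfig, encode, train_dae
from .evaluation import EvaluationReport, mpr, recall_precision_at_r
from .graph_diffusion import (
    AdjacencyMatrix,
    RWRConfig,
    fuse_diffusion_states,
    row_normalize,
    rwr_diffusion,
)
from .pu_imc import (
    AssociationMatrix,
    FactorPair,
    PUIMCConfig,
    SideFeatures,
    fit_puimc,
    predict_rankings,
)

__all__ = [
    "FixtureConfig",
    "PlantedTruth",
    "RecoveryResult",
    "make_network",
    "make_side_features",
    "plant_associations",
    "parameter_recovery_experiment",
]


@dataclass
class FixtureConfig:
    """Shape and noise of one synthetic problem instance.

    The defaults define the standard desk-scale instance used throughout the
    test suite: 300 genes × 120 diseases, two gene networks and one disease
    network, rank-10 planted structure, 5% positive density with 20% of
    positives hidden as evaluation truth.  ``positive_density`` of 0.05 with
    most mass concentrated on few cells mimics the extreme sparsity of
    curated association matrices.
    """

    n_genes: int = 300
    n_diseases: int = 120
    n_networks: int = 2
    n_modules: int = 6
    f_g: int = 40
    f_d: int = 30
    k_true: int = 10
    positive_density: float = 0.05
    feature_noise_sd: float = 0.1
    hidden_fraction: float = 0.2
    p_in: float = 0.25
    p_out: float = 0.02
    disease_tilt: float = 0.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.k_true > min(self.f_g, self.f_d):
            raise ValueError("k_true must not exceed min(f_g, f_d)")
        if not 0 < self.positive_density < 1:
            raise ValueError("positive_density must lie in (0, 1)")
        if self.positive_density * self.n_genes * self.n_diseases < 10:
            raise ValueError("fixture would contain fewer than 10 positives")
        if self.feature_noise_sd < 0:
            raise ValueError("feature_noise_sd must be nonnegative")


@dataclass
class PlantedTruth:
    """Ground truth behind a planted instance."""

    coupling: np.ndarray            # f_g×f_d rank-k_true bilinear form
    true_scores: np.ndarray         # N_g×N_d planted score matrix
    train_pairs: np.ndarray         # (m, 2) observed positives
    hidden_pairs: np.ndarray        # (h, 2) withheld positives


@dataclass
class RecoveryResult:
    """Outcome of the end-to-end parameter-recovery run."""

    report: EvaluationReport
    baseline_mpr: float
    factors: FactorPair
    features: SideFeatures
    hidden_pairs: np.ndarray


def make_network(
    n: int, n_modules: int, p_in: float, p_out: float, seed: int
) -> AdjacencyMatrix:
    """Symmetric planted-partition graph with unit edge weights.

    Nodes are split into ``n_modules`` near-equal contiguous blocks; edges
    appear independently with probability ``p_in`` within a block and
    ``p_out`` across blocks.  No self loops.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if n_modules < 1 or n < 1:
        raise ValueError("n and n_modules must be positive")
    rng = np.random.default_rng(seed)
    membership = np.concatenate(
        [np.full(len(block), b) for b, block in
         enumerate(np.array_split(np.arange(n), n_modules))]
    )
    same = membership[:, None] == membership[None, :]
    prob = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    A = (upper | upper.T).astype(float)
    node_ids = [f"n{i:04d}" for i in range(n)]
    return AdjacencyMatrix(A, node_ids)


def make_side_features(
    n: int, f: int, k_true: int, noise_sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank factor-model feature table plus its latent factors.

    Rows are ``latent (n×k_true) @ loadings (k_true×f)`` plus i.i.d. Gaussian
    noise with standard deviation ``noise_sd``.  Returns ``(features,
    latents)``; the latents are retained so truth can be planted on the same
    structure.
    """
    if k_true > f:
        raise ValueError("k_true must not exceed the feature width f")
    rng = np.random.default_rng(seed)
    latents = rng.standard_normal((n, k_true))
    loadings = rng.standard_normal((k_true, f)) / np.sqrt(k_true)
    features = latents @ loadings
    if noise_sd > 0:
        features = features + noise_sd * rng.standard_normal((n, f))
    return features, latents


def plant_associations(
    gene_feats: np.ndarray,
    disease_feats: np.ndarray,
    k_true: int,
    positive_density: float,
    hidden_fraction: float,
    seed: int,
    disease_tilt: float = 0.0,
) -> tuple[AssociationMatrix, PlantedTruth]:
    """Plant sparse positives from a random low-rank bilinear form.

    Scores ``X·C·Yᵀ`` with a random rank-``k_true`` coupling C; the top
    ``density·N_g·N_d`` cells become positives, of which ``hidden_fraction``
    are withheld as evaluation ground truth.  All other cells are unlabeled.
    ``disease_tilt > 0`` multiplies each disease column by a heavy-tailed
    weight before selection, skewing per-disease positive counts toward the
    few-positives-per-disease regime of curated data.
    """
    rng = np.random.default_rng(seed)
    n_g, f_g = gene_feats.shape
    n_d, f_d = disease_feats.shape
    Bg = rng.standard_normal((f_g, k_true))
    Bd = rng.standard_normal((f_d, k_true))
    C = (Bg @ Bd.T) / k_true
    scores = gene_feats @ C @ disease_feats.T
    if np.ptp(scores) == 0:
        raise ValueError("degenerate instance: all planted scores are equal")
    selection = scores
    if disease_tilt > 0:
        weights = rng.pareto(disease_tilt, size=n_d) + 1.0
        selection = scores * weights[None, :]
    q = int(round(positive_density * n_g * n_d))
    flat = np.argpartition(selection.ravel(), -q)[-q:]
    pairs = np.column_stack(np.unravel_index(flat, scores.shape))
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    n_hidden = int(round(hidden_fraction * q))
    hidden_idx = rng.choice(q, size=n_hidden, replace=False)
    mask = np.zeros(q, dtype=bool)
    mask[hidden_idx] = True
    hidden = pairs[mask]
    train = pairs[~mask]
    P = AssociationMatrix((n_g, n_d), {tuple(p) for p in train})
    truth = PlantedTruth(
        coupling=C, true_scores=scores, train_pairs=train, hidden_pairs=hidden
    )
    return P, truth


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (M - M.mean(axis=0)) / sd


def _network_branch(
    networks: list[AdjacencyMatrix], restart: float, d: int
) -> np.ndarray:
    diff = [
        rwr_diffusion(row_normalize(net), RWRConfig(restart_prob=restart))
        for net in networks
    ]
    fused = fuse_diffusion_states(diff)
    return svd_embed(log_transform(fused), d).node_features


def parameter_recovery_experiment(
    cfg: FixtureConfig,
    model_cfg: PUIMCConfig | None = None,
    shuffle_disease_features: bool = False,
    r: int = 100,
) -> RecoveryResult:
    """Full pipeline on a planted instance; can it rank hidden truth highly?

    Gene side: ``n_networks`` planted-partition networks → RWR (restart 0.05)
    → joint DCA embedding (24 dims), plus the noisy feature table → denoising
    autoencoder codes (16 dims); concatenated and column-standardized to 40
    model features.  Disease side: one network → DCA (16 dims) plus table →
    DAE codes (14 dims) → 30 features.  PU-IMC is then fit on the training
    positives and hidden positives are evaluated against the ranking, next to
    a random-scores baseline on the identical split and exclusions.

    ``shuffle_disease_features`` permutes disease rows after planting — a
    negative control that should push the MPR toward the 50% chance level.
    """
    if model_cfg is None:
        model_cfg = PUIMCConfig(k=20, seed=cfg.seed)
    base = cfg.seed

    gene_table, _ = make_side_features(
        cfg.n_genes, cfg.f_g, cfg.k_true, cfg.feature_noise_sd, base + 1
    )
    disease_table, _ = make_side_features(
        cfg.n_diseases, cfg.f_d, cfg.k_true, cfg.feature_noise_sd, base + 2
    )
    P_train, truth = plant_associations(
        gene_table,
        disease_table,
        cfg.k_true,
        cfg.positive_density,
        cfg.hidden_fraction,
        base + 3,
        disease_tilt=cfg.disease_tilt,
    )

    gene_nets = [
        make_network(cfg.n_genes, cfg.n_modules, cfg.p_in, cfg.p_out, base + 10 + i)
        for i in range(cfg.n_networks)
    ]
    disease_net = make_network(
        cfg.n_diseases, max(2, cfg.n_modules // 2), cfg.p_in, cfg.p_out, base + 30
    )
    gene_net_emb = _network_branch(gene_nets, restart=0.05, d=24)
    disease_net_emb = _network_branch([disease_net], restart=0.05, d=16)

    dae_g = train_dae(
        gene_table,
        DAEConfig(layer_sizes=[32, 16], epochs=80, batch_size=150, seed=base + 40),
    )
    dae_d = train_dae(
        disease_table,
        DAEConfig(layer_sizes=[24, 14], epochs=80, batch_size=150, seed=base + 41),
    )
    gene_codes = encode(gene_table, dae_g)
    disease_codes = encode(disease_table, dae_d)

    Xg = _standardize(np.hstack([gene_net_emb, gene_codes]))
    Yd = _standardize(np.hstack([disease_net_emb, disease_codes]))
    if shuffle_disease_features:
        rng = np.random.default_rng(base + 50)
        Yd = Yd[rng.permutation(len(Yd))]
    feats = SideFeatures(Xg, Yd)

    factors = fit_puimc(P_train, feats, model_cfg)
    exclude = {tuple(p) for p in truth.train_pairs}
    ranked = predict_rankings(factors, feats, exclude=exclude)
    report = recall_precision_at_r(ranked, truth.hidden_pairs, r=r)

    rng = np.random.default_rng(base + 60)
    baseline_ranked = _random_rankings(cfg.n_genes, cfg.n_diseases, exclude, rng)
    baseline = mpr(baseline_ranked, truth.hidden_pairs)
    return RecoveryResult(
        report=report,
        baseline_mpr=baseline,
        factors=factors,
        features=feats,
        hidden_pairs=truth.hidden_pairs,
    )


def _random_rankings(n_genes: int, n_diseases: int, exclude, rng):
    """Rankings from i.i.d. uniform scores, honoring the same exclusions."""
    from .evaluation import RankedPredictions

    excluded_by_d: dict[int, list[int]] = {}
    for g, d in exclude or ():
        excluded_by_d.setdefault(int(d), []).append(int(g))
    rankings = {}
    for d in range(n_diseases):
        mask = np.ones(n_genes, dtype=bool)
        if d in excluded_by_d:
            mask[excluded_by_d[d]] = False
        cand = np.flatnonzero(mask)
        sc = rng.random(len(cand))
        order = np.lexsort((cand, -sc))
        rankings[d] = (cand[order], sc[order])
    return RankedPredictions(rankings=rankings, n_genes=n_genes)
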