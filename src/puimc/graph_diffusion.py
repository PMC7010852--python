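"""Random walk with restart (RWR) over weighted similarity networks.

Every node of a gene–gene (or disease–disease) network is used as the source
of a restarting random walk; the stationary visiting distribution of that walk
is the node's *diffusion state*.  Nodes with similar diffusion states occupy a
similar topological context and are therefore likely to be functionally
related — the premise behind network-based gene prioritization.

Conventions
-----------
Rows are walk sources, columns are walk targets: the walk iterates the row
vector update ``s ← (1 − p_r)·s·B + p_r·δ_i``.  For symmetric networks the
convention is immaterial; for asymmetric weights it is fixed here once and
used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdjacencyMatrix",
    "TransitionMatrix",
    "RWRConfig",
    "DiffusionStateMatrix",
    "row_normalize",
    "rwr_diffusion",
    "fuse_diffusion_states",
]


@dataclass
class AdjacencyMatrix:
    """Weighted adjacency matrix of a similarity network.

    Parameters
    ----------
    weights
        Square matrix of nonnegative edge weights, ``weights[i, j]`` being the
        weight of the edge from node ``i`` to node ``j``.
    node_ids
        Ordered, unique identifiers for the ``n`` nodes.
    """

    weights: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("adjacency matrix contains non-finite entries")
        if np.any(self.weights < 0):
            raise ValueError("negative edge weights are not allowed")
        self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != self.weights.shape[0]:
            raise ValueError(
                f"{len(self.node_ids)} node ids for an "
                f"{self.weights.shape[0]}-node matrix"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node identifiers must be unique")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix B of the random walk."""

    probs: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        row_sums = self.probs.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")


@dataclass
class RWRConfig:
    """Restart-walk parameters.

    ``restart_prob`` (p_r) balances local against global network structure:
    high values keep the walker near its source.  The default 0.05 is the
    value commonly used for gene/disease similarity networks.  Iteration
    stops when the L1 change of every diffusion-state row falls below
    ``tolerance``.
    """

    restart_prob: float = 0.05
    tolerance: float = 1e-6
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must lie in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")


@dataclass
class DiffusionStateMatrix:
    """Stationary RWR distributions, one row per source node."""

    states: np.ndarray
    node_ids: list[str]
    converged: bool = True

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)

    @property
    def n(self) -> int:
        return self.states.shape[0]


def row_normalize(
    adj: AdjacencyMatrix, zero_row_policy: str = "uniform"
) -> TransitionMatrix:
    """Convert edge weights to per-row transition probabilities.

    ``B_ij = A_ij / Σ_j' A_ij'``.  Rows with zero total weight (isolated
    nodes) are undefined under that formula and are filled according to
    ``zero_row_policy``: ``"uniform"`` assigns 1/n to every target (the
    default, keeping the walk irreducible from that node), ``"self_loop"``
    puts all mass on the node itself.
    """
    if zero_row_policy not in ("uniform", "self_loop"):
        raise ValueError(f"unknown zero_row_policy {zero_row_policy!r}")
    A = adj.weights
    n = adj.n
    sums = A.sum(axis=1)
    B = np.zeros_like(A)
    pos = sums > 0
    B[pos] = A[pos] / sums[pos, None]
    if np.any(~pos):
        if zero_row_policy == "uniform":
            B[~pos] = 1.0 / n
        else:
            idx = np.flatnonzero(~pos)
            B[idx, idx] = 1.0
    return TransitionMatrix(B, adj.node_ids)


def rwr_diffusion(trans: TransitionMatrix, cfg: RWRConfig) -> DiffusionStateMatrix:
    """Fixed point of the restart walk for every source node simultaneously.

    Iterates ``S ← (1 − p_r)·S·B + p_r·I`` from ``S = I`` (row ``i`` is the
    walk started at node ``i``) until the largest per-row L1 change drops
    below the tolerance.  Non-convergence is reported via the ``converged``
    flag and a warning, never an exception.
    """
    B = trans.probs
    n = B.shape[0]
    p = cfg.restart_prob
    restart = p * np.eye(n)
    S = np.eye(n)
    converged = False
    for _ in range(cfg.max_iterations):
        S_next = (1.0 - p) * (S @ B) + restart
        delta = np.abs(S_next - S).sum(axis=1).max()
        S = S_next
        if delta < cfg.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RWR did not converge within {cfg.max_iterations} iterations "
            f"(last L1 change {delta:.3g})",
            RuntimeWarning,
        )
    return DiffusionStateMatrix(S, trans.node_ids, converged)


def fuse_diffusion_states(states_list: list[DiffusionStateMatrix]) -> np.ndarray:
    """Concatenate the diffusion states of several networks column-wise.

    All networks must cover the identical ordered node set; the result is the
    ``n × (m·n)`` block matrix consumed by the embedding step, so that one
    joint factorization integrates the m networks.
    """
    if not states_list:
        raise ValueError("need at least one diffusion state matrix")
    ref = states_list[0].node_ids
    for k, st in enumerate(states_list[1:], start=2):
        if st.node_ids != ref:
            missing = sorted(set(ref) ^ set(st.node_ids))
            raise ValueError(
                f"network {k} has a different node set; "
                f"symmetric difference: {missing[:20]}"
            )
    return np.hstack([st.states for st in states_list])
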