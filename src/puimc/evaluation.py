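"""Evaluation metrics and cross-validation protocols for gene rankings.

Three indices: recall@r and precision@r over per-disease top-r gene lists,
and the mean percentile ranking (MPR) of held-out true associations.  MPR is
0% when every hidden gene tops its disease's list, 100% in the worst case,
and 50% in expectation for random scores — which makes it a scale-free
sanity check as well as a performance index.

Three protocols: global three-fold cross-validation over all known pairs,
and two inductive hold-outs restricted to genes (rows) or diseases (columns)
that possess exactly one known association ("new gene" / "new disease").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RankedPredictions",
    "EvaluationReport",
    "CVSplit",
    "threefold_split",
    "single_association_holdout",
    "recall_precision_at_r",
    "percentile_rank",
    "mpr",
]


@dataclass
class RankedPredictions:
    """Per-disease gene rankings, scores descending.

    ``rankings`` maps a disease index to ``(gene_indices, scores)``, both in
    ranked order.  Excluded pairs (e.g. a disease's training positives) are
    simply absent from that disease's candidate list.
    """

    rankings: dict[int, tuple[np.ndarray, np.ndarray]]
    n_genes: int

    def __post_init__(self) -> None:
        for d, (genes, scores) in self.rankings.items():
            if len(genes) != len(scores):
                raise ValueError(f"disease {d}: gene/score length mismatch")
            if np.any(np.diff(scores) > 1e-12):
                raise ValueError(f"disease {d}: scores are not non-increasing")

    def n_candidates(self, disease: int) -> int:
        return len(self.rankings[disease][0])

    def position_of(self, gene: int, disease: int) -> int:
        """1-based rank of ``gene`` in ``disease``'s candidate list."""
        genes = self.rankings[disease][0]
        hits = np.flatnonzero(genes == gene)
        if hits.size == 0:
            raise ValueError(
                f"gene {gene} is not a ranked candidate for disease {disease}"
            )
        return int(hits[0]) + 1


@dataclass
class EvaluationReport:
    """Summary of one evaluation run (all rates on [0, 1]; MPR in percent)."""

    recall: float
    precision: float
    mpr: float
    per_disease_pr: dict[int, float]
    r_threshold: int
    tp: int
    fp: int
    fn: int


@dataclass
class CVSplit:
    """Hidden-pair sets for a validation protocol.

    ``folds`` holds one (m, 2) integer array of (gene, disease) pairs per
    fold; hold-out protocols have a single fold.
    """

    folds: list[np.ndarray]
    protocol: str


def threefold_split(P, seed: int) -> CVSplit:
    """Random partition of the known pairs into three near-equal folds.

    Each known association is hidden in exactly one fold; fold sizes differ
    by at most one.  Deterministic given the seed.
    """
    pairs = P.positive_array()
    if len(pairs) < 3:
        raise ValueError("need at least 3 known associations for a 3-fold split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds = [pairs[idx] for idx in np.array_split(order, 3)]
    return CVSplit(folds=folds, protocol="global")


def single_association_holdout(P, axis: str = "gene") -> CVSplit:
    """Hold out the unique positive of every single-association gene/disease.

    ``axis="gene"`` selects genes whose row of the association matrix has
    exactly one nonzero entry (the "new gene" protocol); ``axis="disease"``
    the analogous columns.  Those pairs form the validation set and are
    hidden during training.
    """
    if axis not in ("gene", "disease"):
        raise ValueError(f"axis must be 'gene' or 'disease', got {axis!r}")
    pairs = P.positive_array()
    col = 0 if axis == "gene" else 1
    n_entities = P.shape[col]
    counts = np.bincount(pairs[:, col], minlength=n_entities)
    selected = counts == 1
    if not selected.any():
        raise ValueError(
            f"no new-{axis} candidates: 0 of {n_entities} {axis}s have exactly "
            f"one association"
        )
    mask = selected[pairs[:, col]]
    return CVSplit(
        folds=[pairs[mask]],
        protocol="new_gene" if axis == "gene" else "new_disease",
    )


def percentile_rank(position: int, n_candidates: int) -> float:
    """Percentile ranking of a 1-based list position, on [0, 100].

    0% for the top of the list (most likely association), 100% for the
    bottom; interior positions interpolate linearly,
    ``100·(position − 1)/(n_candidates − 1)``.
    """
    if n_candidates < 2:
        raise ValueError("percentile rank is undefined for fewer than 2 candidates")
    if not 1 <= position <= n_candidates:
        raise ValueError(f"position {position} outside [1, {n_candidates}]")
    return 100.0 * (position - 1) / (n_candidates - 1)


def _group_hidden(hidden) -> dict[int, list[int]]:
    by_disease: dict[int, list[int]] = {}
    for g, d in hidden:
        by_disease.setdefault(int(d), []).append(int(g))
    if not by_disease:
        raise ValueError("hidden set is empty")
    return by_disease


def mpr(ranked: RankedPredictions, hidden) -> float:
    """Mean percentile ranking of hidden pairs; lower is better.

    Per disease, the mean percentile rank of its hidden genes; the MPR is
    the unweighted mean of those per-disease values over all diseases with
    at least one hidden gene.
    """
    by_disease = _group_hidden(hidden)
    per_disease = []
    for d, genes in by_disease.items():
        if d not in ranked.rankings:
            raise ValueError(f"disease {d} has no ranking")
        n = ranked.n_candidates(d)
        prs = [percentile_rank(ranked.position_of(g, d), n) for g in genes]
        per_disease.append(float(np.mean(prs)))
    return float(np.mean(per_disease))


def recall_precision_at_r(
    ranked: RankedPredictions, hidden, r: int
) -> EvaluationReport:
    """Recall@r and precision@r for hidden pairs, plus the MPR.

    A hidden pair is a true positive when its gene appears in the top-r list
    of its disease.  Every other of the min(r, candidates) slots of an
    evaluated disease (one with at least one hidden gene) counts as a false
    positive; hidden pairs outside the top r are false negatives.
    """
    if r < 1:
        raise ValueError("r must be a positive integer")
    by_disease = _group_hidden(hidden)
    tp = fp = 0
    n_hidden = 0
    per_disease_pr: dict[int, float] = {}
    for d, genes in by_disease.items():
        if d not in ranked.rankings:
            raise ValueError(f"disease {d} has no ranking")
        n = ranked.n_candidates(d)
        positions = [ranked.position_of(g, d) for g in genes]
        tp_d = sum(1 for p in positions if p <= r)
        slots = min(r, n)
        tp += tp_d
        fp += slots - tp_d
        n_hidden += len(genes)
        per_disease_pr[d] = float(
            np.mean([percentile_rank(p, n) for p in positions])
        )
    fn = n_hidden - tp
    recall = tp / n_hidden
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    return EvaluationReport(
        recall=recall,
        precision=precision,
        mpr=float(np.mean(list(per_disease_pr.values()))),
        per_disease_pr=per_disease_pr,
        r_threshold=r,
        tp=tp,
        fp=fp,
        fn=fn,
    )
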