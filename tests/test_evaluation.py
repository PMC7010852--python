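import numpy as np
import pytest

from puimc import (
    AssociationMatrix,
    RankedPredictions,
    mpr,
    percentile_rank,
    recall_precision_at_r,
    single_association_holdout,
    threefold_split,
)


def rankings_from_scores(scores: np.ndarray) -> RankedPredictions:
    """All genes ranked per disease (column) by descending score."""
    n_g, n_d = scores.shape
    rankings = {}
    for d in range(n_d):
        cand = np.arange(n_g)
        order = np.lexsort((cand, -scores[:, d]))
        rankings[d] = (cand[order], scores[order, d])
    return RankedPredictions(rankings, n_genes=n_g)


def rankings_with_positions(n_genes, placed: dict[int, dict[int, int]]):
    """Place gene g at 1-based position p for disease d: {d: {g: p}}."""
    rankings = {}
    for d, placements in placed.items():
        genes = [g for g in range(n_genes) if g not in placements]
        order = [None] * n_genes
        for g, p in placements.items():
            order[p - 1] = g
        it = iter(genes)
        order = [g if g is not None else next(it) for g in order]
        scores = np.linspace(1.0, 0.0, n_genes)
        rankings[d] = (np.array(order), scores)
    return RankedPredictions(rankings, n_genes=n_genes)


class TestThreefoldSplit:
    def P(self, n_pos, n_g=10, n_d=8, seed=0):
        rng = np.random.default_rng(seed)
        cells = rng.choice(n_g * n_d, size=n_pos, replace=False)
        return AssociationMatrix((n_g, n_d), {(int(c // n_d), int(c % n_d)) for c in cells})

    def test_nine_positives_split_evenly(self):
        split = threefold_split(self.P(9), seed=1)
        assert sorted(len(f) for f in split.folds) == [3, 3, 3]

    def test_ten_positives_sizes_differ_by_at_most_one(self):
        split = threefold_split(self.P(10), seed=1)
        assert sorted(len(f) for f in split.folds) == [3, 3, 4]

    def test_folds_partition_positives(self):
        P = self.P(20)
        split = threefold_split(P, seed=3)
        all_pairs = {tuple(p) for f in split.folds for p in f}
        assert all_pairs == P.positives
        assert sum(len(f) for f in split.folds) == 20

    def test_deterministic_given_seed(self):
        P = self.P(15)
        s1, s2 = threefold_split(P, 42), threefold_split(P, 42)
        for f1, f2 in zip(s1.folds, s2.folds):
            np.testing.assert_array_equal(f1, f2)

    def test_rejects_too_few_positives(self):
        with pytest.raises(ValueError, match="at least 3"):
            threefold_split(self.P(2), seed=0)


class TestSingleAssociationHoldout:
    def test_selects_single_association_genes(self):
        # gene row sums (1, 2, 0, 1) → genes 0 and 3, two validation pairs
        P = AssociationMatrix((4, 3), {(0, 1), (1, 0), (1, 2), (3, 2)})
        split = single_association_holdout(P, axis="gene")
        pairs = {tuple(p) for p in split.folds[0]}
        assert pairs == {(0, 1), (3, 2)}
        assert split.protocol == "new_gene"

    def test_no_candidates_is_an_error(self):
        P = AssociationMatrix((2, 2), {(0, 0), (0, 1), (1, 0), (1, 1)})
        with pytest.raises(ValueError, match="no new-gene candidates"):
            single_association_holdout(P, axis="gene")

    def test_transpose_symmetry(self):
        pos = {(0, 1), (1, 0), (1, 2), (3, 2)}
        P = AssociationMatrix((4, 4), pos)
        Pt = AssociationMatrix((4, 4), {(d, g) for g, d in pos})
        by_gene = {tuple(p) for p in single_association_holdout(P, "gene").folds[0]}
        by_disease = {
            (d, g) for g, d in
            (tuple(p) for p in single_association_holdout(Pt, "disease").folds[0])
        }
        assert by_gene == by_disease


class TestRecallPrecisionAtR:
    def test_perfect_top_one(self):
        ranked = rankings_with_positions(5, {0: {2: 1}})
        rep = recall_precision_at_r(ranked, [(2, 0)], r=1)
        assert rep.recall == 1.0 and rep.precision == 1.0
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    def test_miss_just_below_threshold(self):
        ranked = rankings_with_positions(10, {0: {4: 6}})
        rep = recall_precision_at_r(ranked, [(4, 0)], r=5)
        assert rep.recall == 0.0 and rep.precision == 0.0

    def test_hand_enumerated_two_disease_case(self):
        # hidden ranks {1, 3} and {12}, r=10 → TP=2, recall 2/3, precision 2/20
        ranked = rankings_with_positions(15, {0: {3: 1, 7: 3}, 1: {9: 12}})
        rep = recall_precision_at_r(ranked, [(3, 0), (7, 0), (9, 1)], r=10)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.precision == pytest.approx(0.10)
        assert (rep.tp, rep.fp, rep.fn) == (2, 18, 1)

    def test_recall_non_decreasing_in_r(self, rng):
        scores = rng.random((30, 6))
        ranked = rankings_from_scores(scores)
        hidden = [(int(rng.integers(30)), d) for d in range(6)]
        recalls = [recall_precision_at_r(ranked, hidden, r).recall
                   for r in (1, 3, 5, 10, 20, 30)]
        assert all(b >= a for a, b in zip(recalls, recalls[1:]))

    def test_precision_times_slots_equals_tp(self, rng):
        scores = rng.random((30, 6))
        ranked = rankings_from_scores(scores)
        hidden = [(int(rng.integers(30)), d) for d in range(4)]
        rep = recall_precision_at_r(ranked, hidden, r=7)
        assert rep.precision * (rep.tp + rep.fp) == pytest.approx(rep.tp)

    def test_rejects_hidden_pair_outside_candidates(self):
        ranked = rankings_with_positions(5, {0: {1: 1}})
        with pytest.raises(ValueError, match="no ranking"):
            recall_precision_at_r(ranked, [(1, 3)], r=2)


class TestPercentileRank:
    def test_top_is_zero_percent(self):
        assert percentile_rank(1, 100) == 0.0

    def test_bottom_is_hundred_percent(self):
        assert percentile_rank(100, 100) == 100.0

    def test_midpoint(self):
        assert percentile_rank(2, 3) == 50.0

    def test_rejects_degenerate_candidate_sets(self):
        with pytest.raises(ValueError):
            percentile_rank(1, 1)
        with pytest.raises(ValueError):
            percentile_rank(5, 4)


class TestMPR:
    def test_all_top_ranked_is_zero(self):
        ranked = rankings_with_positions(8, {0: {3: 1}, 1: {5: 1}})
        assert mpr(ranked, [(3, 0), (5, 1)]) == 0.0

    def test_hand_computed_two_disease_value(self):
        # PR 0% (rank 1 of 5) and PR 50% (rank 3 of 5) → MPR 25%
        ranked = rankings_with_positions(5, {0: {2: 1}, 1: {4: 3}})
        assert mpr(ranked, [(2, 0), (4, 1)]) == pytest.approx(25.0)

    def test_antisymmetry_under_ranking_reversal(self, rng):
        scores = rng.random((20, 5))
        hidden = [(int(rng.integers(20)), d) for d in range(5)]
        forward = mpr(rankings_from_scores(scores), hidden)
        backward = mpr(rankings_from_scores(-scores), hidden)
        assert forward + backward == pytest.approx(100.0)

    def test_invariant_under_monotone_score_transform(self, rng):
        scores = rng.random((20, 5))
        hidden = [(int(rng.integers(20)), d) for d in range(5)]
        a = mpr(rankings_from_scores(scores), hidden)
        b = mpr(rankings_from_scores(np.exp(3 * scores)), hidden)
        assert a == pytest.approx(b)

    def test_invariant_under_disease_permutation(self, rng):
        scores = rng.random((20, 5))
        hidden = [(int(rng.integers(20)), d) for d in range(5)]
        perm = rng.permutation(5)
        a = mpr(rankings_from_scores(scores), hidden)
        b = mpr(rankings_from_scores(scores[:, perm]),
                [(g, int(np.flatnonzero(perm == d)[0])) for g, d in hidden])
        assert a == pytest.approx(b)

    def test_random_scores_near_fifty_percent(self):
        # chance level across 10 seeds: mean within Monte-Carlo error of 50%
        values = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = rng.random((100, 50))
            hidden = [(int(rng.integers(100)), d) for d in range(50)]
            values.append(mpr(rankings_from_scores(scores), hidden))
        assert abs(np.mean(values) - 50.0) < 3.0

    def test_rejects_empty_hidden_set(self):
        ranked = rankings_with_positions(5, {0: {1: 1}})
        with pytest.raises(ValueError, match="empty"):
            mpr(ranked, [])
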