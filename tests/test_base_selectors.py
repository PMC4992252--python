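"""Baseline filters, wrapper searches and mRMR against hand traces and
brute-force oracles."""

import itertools

import numpy as np
import pytest

from pairfs import (
    Dataset,
    DiscretizationSpec,
    EvalConfig,
    backward_elimination,
    chi_squared_rank,
    eval_subset,
    forward_search,
    fsdd_rank,
    gain_ratio_rank,
    mrmr_rank,
    relief_rank,
)
from pairfs.prefilter import mi_score
from conftest import make_random_ds


def two_class_ds(feature_cols, labels, names=None):
    cols = [np.asarray(c, dtype=float) for c in feature_cols]
    names = names or [f"f{i}" for i in range(len(cols))]
    return Dataset(np.column_stack(cols), labels, names)


class TestChiSquared:
    def test_perfect_diagonal_table(self):
        # binned feature vs class contingency [[10, 0], [0, 10]]
        ds = two_class_ds([[0] * 10 + [1] * 10, [0.0] * 20],
                          ["A"] * 10 + ["B"] * 10)
        rk = chi_squared_rank(ds, DiscretizationSpec(2))
        assert rk.scores[rk.order.tolist().index(0)] == pytest.approx(20.0)

    def test_proportional_counts_score_zero(self):
        ds = two_class_ds([[0, 0, 1, 1, 0, 0, 1, 1], [0.0] * 8],
                          ["A"] * 4 + ["B"] * 4)
        rk = chi_squared_rank(ds, DiscretizationSpec(2))
        assert rk.scores == pytest.approx([0.0, 0.0])

    def test_matches_scipy_contingency(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(21)
        codes = rng.integers(0, 3, 60)
        y = rng.integers(0, 2, 60)
        ds = Dataset(codes[:, None].astype(float),
                     [f"c{c}" for c in y], ["f"])
        rk = chi_squared_rank(ds, DiscretizationSpec(3))
        table = np.array([[np.sum((codes == b) & (y == c)) for c in (0, 1)]
                          for b in range(3)])
        expected = chi2_contingency(table, correction=False).statistic
        assert rk.scores[0] == pytest.approx(expected)

    def test_separator_beats_noise_all_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sep = np.repeat([0.0, 3.0], 15) + rng.normal(0, 0.3, 30)
            noise = rng.normal(size=30)
            ds = two_class_ds([noise, sep], ["A"] * 15 + ["B"] * 15)
            rk = chi_squared_rank(ds)
            assert rk.order[0] == 1


class TestGainRatio:
    def test_feature_identical_to_class_is_one(self):
        ds = two_class_ds([[0, 0, 1, 1], [0.0] * 4], ["A", "A", "B", "B"])
        rk = gain_ratio_rank(ds, DiscretizationSpec(2))
        assert rk.scores[rk.order.tolist().index(0)] == pytest.approx(1.0)

    def test_constant_feature_is_zero(self):
        ds = two_class_ds([[5.0] * 4, [0, 0, 1, 1]], ["A", "A", "B", "B"])
        rk = gain_ratio_rank(ds, DiscretizationSpec(2))
        assert rk.scores[rk.order.tolist().index(0)] == pytest.approx(0.0)

    def test_hand_joint_table(self):
        codes = [0, 0, 1, 1, 1, 1]
        labels = ["A", "A", "A", "B", "B", "B"]
        ds = two_class_ds([codes, [0.0] * 6], labels)
        rk = gain_ratio_rank(ds, DiscretizationSpec(2))
        # oracle: IG / H(F) computed from the explicit joint table
        ig = mi_score(codes, labels)
        hf = -(2 / 6) * np.log2(2 / 6) - (4 / 6) * np.log2(4 / 6)
        assert rk.scores[rk.order.tolist().index(0)] == pytest.approx(ig / hf)


class TestRelief:
    def test_hand_trace_single_feature(self):
        ds = two_class_ds([[0, 0, 1, 1]], ["A", "A", "B", "B"])
        rk = relief_rank(ds, k_neighbors=1)
        assert rk.scores[0] == pytest.approx(1.0)

    def test_disjoint_ranges_positive_constant_zero(self):
        rng = np.random.default_rng(7)
        sep = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(5, 6, 10)])
        const = np.full(20, 2.0)
        ds = two_class_ds([sep, const], ["A"] * 10 + ["B"] * 10)
        rk = relief_rank(ds, k_neighbors=3)
        scores = {f: s for f, s in zip(rk.order, rk.scores)}
        assert scores[0] > 0
        assert scores[1] == pytest.approx(0.0)

    def test_separator_beats_noise_all_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sep = np.repeat([0.0, 2.0], 12) + rng.normal(0, 0.4, 24)
            ds = two_class_ds([rng.normal(size=24), sep],
                              ["A"] * 12 + ["B"] * 12)
            assert relief_rank(ds).order[0] == 1

    def test_small_class_rejected(self):
        ds = two_class_ds([[0, 1, 2, 3]], ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="ReliefF"):
            relief_rank(ds, k_neighbors=2)


class TestFsdd:
    def test_equal_means_negative(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 2, 20)])
        ds = two_class_ds([x], ["A"] * 20 + ["B"] * 20)
        assert fsdd_rank(ds).scores[0] < 0

    def test_two_point_classes(self):
        # raw between-class variance 0.25 scales to 1.0 after z-normalization
        ds = two_class_ds([[0, 0, 1, 1]], ["A", "A", "B", "B"])
        assert fsdd_rank(ds).scores[0] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.5, 1, 15)])
        ds1 = two_class_ds([x], ["A"] * 15 + ["B"] * 15)
        ds2 = two_class_ds([7.0 * x - 3.0], ["A"] * 15 + ["B"] * 15)
        assert fsdd_rank(ds1).scores[0] == pytest.approx(
            fsdd_rank(ds2).scores[0])


class TestEvalSubset:
    def test_singleton_separator(self, small_ds, knn1):
        assert eval_subset(small_ds, [0], knn1) == 1.0

    def test_full_subset_consistency(self, small_ds, knn3):
        from pairfs._eval import cv_accuracy

        assert eval_subset(small_ds, list(range(4)), knn3) == cv_accuracy(
            small_ds.values, small_ds.label_codes(), knn3)

    def test_xor_pair_beats_its_singletons(self, xor_ds, knn3):
        from pairfs import xor_pair_indices

        ds, roles = xor_ds
        p, q = xor_pair_indices(ds, roles)[0]
        joint = eval_subset(ds, [p, q], knn3)
        assert joint > max(eval_subset(ds, [p], knn3),
                           eval_subset(ds, [q], knn3))

    def test_empty_subset_rejected(self, small_ds, knn1):
        with pytest.raises(ValueError):
            eval_subset(small_ds, [], knn1)


# --- greedy oracles -------------------------------------------------------

def forward_oracle(ds, cfg):
    """Independent greedy forward loop (strict improvement)."""
    chosen, current = [], 0.0
    while True:
        cands = [(eval_subset(ds, chosen + [x], cfg), x)
                 for x in range(ds.n_features) if x not in chosen]
        best = max(cands, key=lambda t: (t[0], -t[1]), default=None)
        if best is None or best[0] <= current:
            return chosen
        chosen.append(best[1])
        current = best[0]


def backward_oracle(ds, cfg):
    """Independent greedy backward loop (non-worsening removals)."""
    chosen = list(range(ds.n_features))
    current = eval_subset(ds, chosen, cfg)
    while len(chosen) > 1:
        cands = [(eval_subset(ds, [f for f in chosen if f != x], cfg), x)
                 for x in chosen]
        best = max(cands, key=lambda t: (t[0], -t[1]))
        if best[0] < current:
            return chosen
        chosen.remove(best[1])
        current = best[0]
    return chosen


class TestForwardSearch:
    def test_perfect_singleton_stops_after_one_step(self, small_ds, knn1):
        res = forward_search(small_ds, knn1)
        assert res.chosen[0] == 0 and len(res.trace) >= 1
        assert res.trace[0].accuracy == 1.0 and len(res.trace) == 1

    def test_all_constant_features_select_nothing(self, knn3):
        ds = Dataset(np.zeros((8, 3)), ["A"] * 4 + ["B"] * 4,
                     ["a", "b", "c"])
        res = forward_search(ds, knn3)
        assert res.chosen == [] and res.trace == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_and_bounded_by_exhaustive(self, seed, knn3):
        ds = make_random_ds(20, 6, seed=seed)
        res = forward_search(ds, knn3)
        assert res.chosen == forward_oracle(ds, knn3)
        best = max(
            eval_subset(ds, list(s), knn3)
            for r in range(1, 7)
            for s in itertools.combinations(range(6), r)
        )
        assert res.accuracy <= best + 1e-12

    def test_trace_monotone(self, knn3):
        ds = make_random_ds(24, 8, seed=17)
        res = forward_search(ds, knn3)
        accs = [s.accuracy for s in res.trace]
        assert accs == sorted(accs)


class TestBackwardElimination:
    def test_redundant_separators_reduce_to_one(self, knn1):
        sep = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        ds = Dataset(np.column_stack([sep, sep]), ["A"] * 4 + ["B"] * 4,
                     ["s1", "s2"])
        res = backward_elimination(ds, knn1)
        assert res.chosen == [1]
        assert all(s.accuracy == 1.0 for s in res.trace)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed, knn3):
        ds = make_random_ds(20, 6, seed=100 + seed)
        assert backward_elimination(ds, knn3).chosen == backward_oracle(
            ds, knn3)

    def test_immediate_stop_keeps_all(self, knn1):
        # every removal of a needed XOR-style column hurts: build features
        # where each one is required for perfect 1-NN separation
        ds = two_class_ds([[0, 0, 1, 1, 2, 2, 3, 3],
                           [0, 1, 0, 1, 0, 1, 0, 1]],
                          ["A", "B", "B", "A", "A", "B", "B", "A"])
        res = backward_elimination(ds, knn1)
        if len(res.chosen) == 2:  # no non-worsening removal at step 1
            assert [s.action for s in res.trace] == ["start"]


class TestMrmr:
    def test_m1_reduces_to_mi_ranking(self, small_ds):
        from pairfs.prefilter import mi_ranking

        rk = mrmr_rank(small_ds, DiscretizationSpec(2), 1)
        assert rk.order[0] == mi_ranking(small_ds,
                                         DiscretizationSpec(2)).order[0]

    def test_exact_copy_penalized_below_weaker_feature(self):
        """f2 duplicates f1 (score I(f1;C) - H(f1) <= 0); the weaker but
        non-redundant f3 is picked second."""
        f1 = [0, 0, 1, 1, 2, 2, 3, 3]
        f3 = [0, 0, 0, 1, 1, 1, 1, 0]
        ds = two_class_ds([f1, f1, f3], ["A"] * 4 + ["B"] * 4,
                          ["f1", "f2", "f3"])
        rk = mrmr_rank(ds, DiscretizationSpec(4), 3)
        assert rk.order.tolist() == [0, 2, 1]

    def test_deterministic_pick_order(self):
        ds = make_random_ds(30, 10, seed=33)
        a = mrmr_rank(ds, DiscretizationSpec(3), 10)
        b = mrmr_rank(ds, DiscretizationSpec(3), 10)
        assert a.order.tolist() == b.order.tolist()

    def test_m_out_of_range(self, small_ds):
        with pytest.raises(ValueError):
            mrmr_rank(small_ds, DiscretizationSpec(2), 9)


class TestRankingInvariants:
    @pytest.mark.parametrize("ranker", [
        chi_squared_rank, gain_ratio_rank,
        lambda ds: relief_rank(ds, 3), lambda ds: fsdd_rank(ds)])
    def test_filters_return_full_permutation(self, ranker):
        ds = make_random_ds(24, 9, seed=50)
        rk = ranker(ds)
        assert sorted(rk.order.tolist()) == list(range(9))
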