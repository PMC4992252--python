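"""Pair-table-aware selector variants: hand traces, identity limits, and
brute-force oracle equivalence."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairfs import (
    DiscretizationSpec,
    EvalConfig,
    PairTable,
    Ranking,
    backward_elimination,
    build_pair_table,
    mrmr_rank,
    modified_backward_elimination,
    modified_filter_rank,
    modified_forward_search,
    modified_mrmr,
    pairwise_reorder,
    xor_pair_indices,
)
from pairfs.modified_selectors import FILTERS
from conftest import make_random_ds


def reorder_oracle(order, rows, t):
    """Literal pop/scan loop over the top-t rows, kept independent of the
    production implementation."""
    pool = rows[:t]
    chosen = deque(order)
    out = []
    while chosen:
        f = chosen.popleft()
        out.append(f)
        for i, j, _ in pool:
            if f in (i, j):
                partner = j if f == i else i
                if partner in chosen:
                    out.append(partner)
                    chosen.remove(partner)
    return out


def table_from_rows(rows, n):
    return PairTable(rows=rows, n_features=n, check_sorted=False)


class TestPairwiseReorder:
    def test_t_zero_is_identity(self):
        base = Ranking(order=[3, 1, 2, 4, 5])
        pt = table_from_rows([(3, 5, 0.9), (2, 4, 0.8)], 6)
        assert pairwise_reorder(base, pt, 0).order.tolist() == [3, 1, 2, 4, 5]

    def test_hand_trace(self):
        base = Ranking(order=[3, 1, 2, 4, 5])
        pt = table_from_rows([(3, 5, 0.9), (2, 4, 0.8)], 6)
        assert pairwise_reorder(base, pt, 2).order.tolist() == [3, 5, 1, 2, 4]

    def test_partner_order_follows_table_order(self):
        base = Ranking(order=[0, 1, 2])
        pt = table_from_rows([(0, 1, 0.9), (0, 2, 0.8)], 3)
        assert pairwise_reorder(base, pt, 2).order.tolist() == [0, 1, 2]

    def test_missing_feature_reported(self):
        base = Ranking(order=[0, 1, 5])
        pt = table_from_rows([(0, 1, 0.9)], 3)
        with pytest.raises(ValueError, match="5"):
            pairwise_reorder(base, pt, 1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_oracle_and_is_permutation(self, data):
        n = data.draw(st.integers(2, 12))
        order = data.draw(st.permutations(range(n)))
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        rows = data.draw(st.lists(st.sampled_from(all_pairs), unique=True,
                                  max_size=12))
        accs = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=len(rows),
            max_size=len(rows)))
        table_rows = sorted(
            [(i, j, round(v, 3)) for (i, j), v in zip(rows, accs)],
            key=lambda r: (-r[2], r[0], r[1]))
        t = data.draw(st.integers(0, len(table_rows)))
        pt = table_from_rows(table_rows, n)
        got = pairwise_reorder(Ranking(order=list(order)), pt, t).order.tolist()
        assert got == reorder_oracle(list(order), table_rows, t)
        assert sorted(got) == list(range(n))


class TestModifiedFilterRank:
    def test_composition_and_t0_identity(self, xor_ds, knn3):
        ds, _ = xor_ds
        pt = build_pair_table(ds, knn3)
        for name, ranker in FILTERS.items():
            base = ranker(ds)
            mod = modified_filter_rank(ds, name, pt, 5)
            assert mod.order.tolist() == pairwise_reorder(
                base, pt, 5).order.tolist()
            assert modified_filter_rank(ds, name, pt, 0).order.tolist() == \
                base.order.tolist()

    def test_unknown_method(self, xor_ds):
        ds, _ = xor_ds
        pt = build_pair_table(ds, EvalConfig(classifier="knn"))
        with pytest.raises(ValueError, match="unknown filter"):
            modified_filter_rank(ds, "anova", pt, 5)


class TestModifiedForward:
    def test_single_perfect_row_one_step(self, small_ds, knn1):
        pt = table_from_rows([(0, 2, 1.0)], 4)
        res = modified_forward_search(small_ds, pt, 1, knn1)
        assert sorted(res.chosen) == [0, 2]
        assert len(res.trace) == 1 and res.trace[0].accuracy == 1.0

    def test_overlapping_moves_allow_odd_sizes(self, knn3):
        ds = make_random_ds(30, 6, seed=3)
        pt = build_pair_table(ds, knn3)
        res = modified_forward_search(ds, pt, len(pt.rows), knn3)
        sizes = [len(s.features) for s in res.trace]
        assert all(sz in (1, 2) for sz in sizes)
        assert len(res.chosen) == sum(sizes)

    def test_first_move_is_planted_pair(self, xor_ds, knn3):
        ds, roles = xor_ds
        p, q = xor_pair_indices(ds, roles)[0]
        pt = build_pair_table(ds, knn3)
        res = modified_forward_search(ds, pt, 20, knn3, max_steps=1)
        assert tuple(sorted(res.trace[0].features)) == (p, q)

    def test_empty_pool_rejected(self, small_ds, knn1):
        pt = table_from_rows([], 4)
        with pytest.raises(ValueError, match="raise T"):
            modified_forward_search(small_ds, pt, 1, knn1)


class TestModifiedBackward:
    def test_initial_set_is_pool_union(self, small_ds, knn1):
        pt = table_from_rows([(0, 1, 0.9), (0, 2, 0.8), (1, 2, 0.7)], 4)
        res = modified_backward_elimination(small_ds, pt, 3, knn1)
        assert set(res.trace[0].features) == {0, 1, 2}

    def test_full_pool_reduces_to_original(self, knn3):
        for seed in range(3):
            ds = make_random_ds(20, 10, seed=200 + seed)
            pt = build_pair_table(ds, knn3)
            mod = modified_backward_elimination(ds, pt, len(pt.rows), knn3)
            orig = backward_elimination(ds, knn3)
            assert mod.chosen == orig.chosen

    def test_eliminates_planted_duplicates(self, knn1):
        rng = np.random.default_rng(9)
        from pairfs import Dataset

        sep = np.repeat([0.0, 1.0], 6)
        ds = Dataset(np.column_stack([sep, sep, rng.normal(size=12)]),
                     ["A"] * 6 + ["B"] * 6, ["s1", "s2", "n"])
        pt = build_pair_table(ds, knn1)
        res = modified_backward_elimination(ds, pt, len(pt.rows), knn1)
        assert len(res.chosen) < len(res.trace[0].features)


class TestModifiedMrmr:
    def test_toy_top_pair_selected(self):
        """With the pool's top row holding the two most relevant, mutually
        non-redundant features, m=2 returns exactly those two."""
        from conftest import make_random_ds
        from pairfs import Dataset

        f1 = np.array([0, 0, 1, 1, 2, 2, 3, 3], dtype=float)
        f2 = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
        f3 = np.array([0, 0, 0, 1, 1, 1, 1, 0], dtype=float)
        ds = Dataset(np.column_stack([f1, f2, f3]),
                     ["A"] * 4 + ["B"] * 4, ["f1", "f2", "f3"])
        pt = table_from_rows([(0, 2, 0.9), (0, 1, 0.5), (1, 2, 0.4)], 3)
        rk = modified_mrmr(ds, DiscretizationSpec(4), pt, 3, 2)
        assert sorted(rk.order.tolist()) == [0, 2]

    def test_full_pool_m1_matches_original_first_pick(self, small_ds, knn3):
        pt = build_pair_table(small_ds, knn3)
        disc = DiscretizationSpec(2)
        mod = modified_mrmr(small_ds, disc, pt, len(pt.rows), 1)
        assert mod.order[0] == mrmr_rank(small_ds, disc, 1).order[0]

    @pytest.mark.parametrize("m", [1, 2, 3, 5])
    def test_length_contract_no_duplicates(self, m, knn3):
        ds = make_random_ds(24, 6, seed=77)
        pt = build_pair_table(ds, knn3)
        rk = modified_mrmr(ds, DiscretizationSpec(3), pt, len(pt.rows), m)
        assert len(rk.order) == m
        assert len(set(rk.order.tolist())) == m

    def test_pool_too_small_for_m(self, small_ds):
        pt = table_from_rows([(0, 1, 0.9)], 4)
        with pytest.raises(ValueError, match="raise T"):
            modified_mrmr(small_ds, DiscretizationSpec(2), pt, 1, 3)
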