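"""Pair-table-aware variants of the baseline selection algorithms.

Each variant consults the top ``T`` rows of the pairwise pre-evaluation
table.  The filter variants reorder the original ranking so that every
placed feature immediately pulls in its strongest partners; the wrapper and
mRMR variants draw their candidate moves from the top rows instead of from
single features.  With ``T = 0`` (filters) or a pool covering every row
(backward elimination) the variants reduce exactly to the originals.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._eval import EvalConfig
from .base_selectors import (
    SelectionResult,
    Step,
    backward_elimination,
    chi_squared_rank,
    eval_subset,
    fsdd_rank,
    gain_ratio_rank,
    relief_rank,
)
from .core_io import Dataset, DiscretizationSpec, Ranking, discretize_codes
from .pairtable import PairTable, top_pairs
from .prefilter import mi_score

__all__ = [
    "pairwise_reorder",
    "modified_filter_rank",
    "modified_forward_search",
    "modified_backward_elimination",
    "modified_mrmr",
    "FILTERS",
]

#: filter name -> ranking function (extra keyword arguments pass through)
FILTERS = {
    "chi2": chi_squared_rank,
    "gain_ratio": gain_ratio_rank,
    "relief": relief_rank,
    "fsdd": fsdd_rank,
}

#: default number of top table rows consulted by every modified method
DEFAULT_TOP_PAIRS = 1000


def _check_coverage(order: Sequence[int], pt: PairTable) -> None:
    for f in order:
        if f >= pt.n_features:
            name = (pt.feature_names[f] if pt.feature_names
                    and f < len(pt.feature_names) else f"index {f}")
            raise ValueError(
                f"pair table (N={pt.n_features}) does not cover feature {name}"
            )


def pairwise_reorder(base: Ranking, pt: PairTable,
                     t: int = DEFAULT_TOP_PAIRS) -> Ranking:
    """Reorder a filter ranking so top pairs keep their partners together.

    Walk the base ranking: pop its head ``f`` and place it; then scan the
    top-``t`` rows in table order and, for every row containing ``f`` whose
    partner is still unplaced, place the partner too (removing it from the
    queue).  Repeat until the queue is empty.  The output is a permutation
    of the input; ``t = 0`` returns the base ranking unchanged.
    """
    _check_coverage(base.order, pt)
    pool = top_pairs(pt, t).rows
    in_base = set(int(f) for f in base.order)
    partners: dict[int, list[int]] = {}
    for i, j, _ in pool:                      # table order preserved per feature
        if i in in_base and j in in_base:
            partners.setdefault(i, []).append(j)
            partners.setdefault(j, []).append(i)
    remaining = set(in_base)
    out: list[int] = []
    for f in (int(x) for x in base.order):
        if f not in remaining:
            continue
        out.append(f)
        remaining.discard(f)
        for p in partners.get(f, ()):
            if p in remaining:
                out.append(p)
                remaining.discard(p)
    return Ranking(order=np.array(out), scores=None)


def modified_filter_rank(ds: Dataset, method: str, pt: PairTable,
                         t: int = DEFAULT_TOP_PAIRS, **params) -> Ranking:
    """Pair-table reordering of a named filter's ranking.

    ``method`` is one of ``chi2 | gain_ratio | relief | fsdd``; extra
    keyword arguments go to the underlying filter (e.g. ``disc``,
    ``k_neighbors``, ``beta``).
    """
    if method not in FILTERS:
        raise ValueError(
            f"unknown filter {method!r}; choose from {sorted(FILTERS)}"
        )
    base = FILTERS[method](ds, **params)
    return pairwise_reorder(base, pt, t)


def _candidate_moves(pool, chosen: set[int]):
    """New-feature sets induced by pool rows, deduplicated, table order."""
    seen: set[frozenset] = set()
    moves: list[tuple[int, ...]] = []
    for i, j, _ in pool:
        new = tuple(f for f in (i, j) if f not in chosen)
        if not new:
            continue
        key = frozenset(new)
        if key in seen:
            continue
        seen.add(key)
        moves.append(new)
    return moves


def modified_forward_search(ds: Dataset, pt: PairTable,
                            t: int = DEFAULT_TOP_PAIRS,
                            cfg: EvalConfig | None = None,
                            max_steps: int | None = None) -> SelectionResult:
    """Forward selection whose moves come from the top table rows.

    A row ``(i, j)`` proposes adding ``{i, j} \\ CHOSEN`` (one or two new
    features; rows fully inside the current subset are skipped).  The best
    move by cross-validated accuracy is accepted while it strictly improves;
    one-feature overlaps mean final subsets may have odd size.  ``max_steps``
    optionally caps the number of accepted steps.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    cfg = cfg or EvalConfig()
    pool = top_pairs(pt, t).rows
    usable = {f for i, j, _ in pool for f in (i, j) if f < ds.n_features}
    if not usable:
        raise ValueError(
            "no dataset feature occurs in the top-T pair pool; raise T"
        )
    chosen: list[int] = []
    trace: list[Step] = []
    current = 0.0
    while max_steps is None or len(trace) < max_steps:
        best_move, best_acc = None, current
        for move in _candidate_moves(pool, set(chosen)):
            acc = eval_subset(ds, chosen + list(move), cfg)
            if acc > best_acc:
                best_move, best_acc = move, acc
        if best_move is None:
            break
        chosen.extend(best_move)
        trace.append(Step("add", best_move, best_acc))
        current = best_acc
    return SelectionResult(chosen, trace)


def modified_backward_elimination(ds: Dataset, pt: PairTable,
                                  t: int = DEFAULT_TOP_PAIRS,
                                  cfg: EvalConfig | None = None
                                  ) -> SelectionResult:
    """Backward elimination started from the union of top-row features.

    The initial subset is every feature occurring in the top-``t`` rows
    (this is where the bulk of the reduction comes from); ordinary backward
    elimination then runs restricted to that subset.  A pool covering all
    rows makes this identical to the original algorithm.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    pool = top_pairs(pt, t)
    initial = sorted(f for f in pool.features() if f < ds.n_features)
    if not initial:
        raise ValueError("top-T pair pool covers no dataset feature; raise T")
    return backward_elimination(ds, cfg, initial=initial)


def modified_mrmr(ds: Dataset, disc: DiscretizationSpec | None = None,
                  pt: PairTable | None = None, t: int = DEFAULT_TOP_PAIRS,
                  m: int = 10) -> Ranking:
    """mRMR whose candidate moves come from the top table rows.

    Moves are generated as in :func:`modified_forward_search` but scored by
    the summed MID criterion of their new features against the current
    selection, ``sum_x [I(x; C) - mean_{s in S} I(x; s)]``.  There is no
    stopping rule: the best move is accepted each step until ``m`` features
    accumulate; a final two-feature move that would overshoot is truncated,
    keeping its higher-relevance feature.
    """
    if pt is None:
        raise ValueError("modified mRMR requires a pair table")
    if t < 1:
        raise ValueError("t must be >= 1")
    disc = disc or DiscretizationSpec()
    pool = top_pairs(pt, t).rows
    covered = {f for i, j, _ in pool for f in (i, j) if f < ds.n_features}
    if m > len(covered):
        raise ValueError(
            f"m={m} exceeds the {len(covered)} features covered by the "
            f"top-T pool; raise T"
        )
    codes = discretize_codes(ds, disc)
    rel = np.array([mi_score(codes[:, f], ds.labels)
                    for f in range(ds.n_features)])
    mi_cache: dict[tuple[int, int], float] = {}

    def mi_ff(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = mi_score(codes[:, key[0]], codes[:, key[1]])
        return mi_cache[key]

    def mid(x: int, chosen: list[int]) -> float:
        if not chosen:
            return float(rel[x])
        return float(rel[x] - sum(mi_ff(x, s) for s in chosen) / len(chosen))

    chosen: list[int] = []
    while len(chosen) < m:
        best_move, best_score = None, -np.inf
        for move in _candidate_moves(pool, set(chosen)):
            score = sum(mid(x, chosen) for x in move)
            if score > best_score:
                best_move, best_score = move, score
        if best_move is None:
            raise ValueError(
                f"pair pool exhausted with {len(chosen)} of {m} features"
            )
        new = sorted(best_move, key=lambda x: (-rel[x], x))
        chosen.extend(new[: m - len(chosen)])
    return Ranking(order=np.array(chosen), scores=None)
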