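"""Exhaustive pairwise pre-evaluation: the table of two-feature accuracies.

Every unordered feature pair ``(i, j)`` is scored by the cross-validated
accuracy of a classifier trained on exactly those two columns.  The sorted
table is the pre-evaluation information that the modified selection
algorithms consume: its top rows are the pairs whose joint behaviour is most
informative about the class, including interactions that no univariate
score can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from ._eval import EvalConfig, cv_accuracy
from .core_io import Dataset

__all__ = ["PairTable", "EvalConfig", "evaluate_pair", "build_pair_table",
           "top_pairs", "pair_count"]


@dataclass
class PairTable:
    """Rows ``(i, j, v)`` with ``i < j`` and ``v`` the pair's accuracy.

    Rows are sorted by accuracy descending, ties by ``(i, j)`` ascending.
    A complete table over ``N`` features has ``N (N - 1) / 2`` rows.
    """

    rows: list[tuple[int, int, float]]
    n_features: int
    feature_names: list[str] | None = None
    meta: dict = field(default_factory=dict)
    check_sorted: bool = True

    def __post_init__(self) -> None:
        seen = set()
        for i, j, v in self.rows:
            if not (0 <= i < j < self.n_features):
                raise ValueError(f"invalid pair ({i}, {j}) for N={self.n_features}")
            if (i, j) in seen:
                raise ValueError(f"duplicate unordered pair ({i}, {j})")
            seen.add((i, j))
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"accuracy {v} outside [0, 1]")
        if self.check_sorted:
            key = [(-v, i, j) for i, j, v in self.rows]
            if key != sorted(key):
                raise ValueError("rows not sorted by accuracy desc, (i, j) asc")
        if self.feature_names is not None and len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length mismatch")

    def __len__(self) -> int:
        return len(self.rows)

    def features(self) -> set[int]:
        """Set of feature indices occurring in at least one row."""
        out: set[int] = set()
        for i, j, _ in self.rows:
            out.add(i)
            out.add(j)
        return out


def pair_count(n_features: int) -> int:
    """Number of unordered feature pairs, C(N, 2)."""
    return n_features * (n_features - 1) // 2


def evaluate_pair(ds: Dataset, i: int, j: int, cfg: EvalConfig) -> float:
    """Cross-validated accuracy using exactly the two columns ``i`` and ``j``.

    Symmetric in ``(i, j)`` and deterministic given its inputs.
    """
    if i == j:
        raise ValueError("a pair needs two distinct features")
    for k in (i, j):
        if not 0 <= k < ds.n_features:
            raise IndexError(f"feature index {k} out of range")
    a, b = (i, j) if i < j else (j, i)
    return cv_accuracy(ds.values[:, [a, b]], ds.label_codes(), cfg)


def _eval_chunk(values: np.ndarray, y: np.ndarray, pairs, cfg: EvalConfig):
    return [cv_accuracy(values[:, [i, j]], y, cfg) for i, j in pairs]


def build_pair_table(ds: Dataset, cfg: EvalConfig | None = None,
                     workers: int = 1) -> PairTable:
    """Score every unordered pair and return the sorted table.

    Pairs are enumerated in lexicographic ``(i, j)`` order, evaluated in
    order-preserving chunks (parallelised with joblib when ``workers > 1``)
    and globally sorted afterwards, so the result is identical for any
    worker count.
    """
    if ds.n_features < 2:
        raise ValueError("need at least 2 features to build a pair table")
    cfg = cfg or EvalConfig()
    y = ds.label_codes()
    pairs = [(i, j) for i in range(ds.n_features)
             for j in range(i + 1, ds.n_features)]
    if workers <= 1:
        accs = _eval_chunk(ds.values, y, pairs, cfg)
    else:
        chunks = [pairs[k::workers * 4] for k in range(workers * 4)]
        # round-robin chunks keep load even; reassemble in original order
        results = Parallel(n_jobs=workers)(
            delayed(_eval_chunk)(ds.values, y, chunk, cfg) for chunk in chunks
        )
        accs = [0.0] * len(pairs)
        for k, res in enumerate(results):
            for pos, v in zip(range(k, len(pairs), workers * 4), res):
                accs[pos] = v
    rows = [(i, j, float(v)) for (i, j), v in zip(pairs, accs)]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return PairTable(rows=rows, n_features=ds.n_features,
                     feature_names=list(ds.feature_names),
                     meta=cfg.describe())


def top_pairs(pt: PairTable, t: int) -> PairTable:
    """First ``min(t, len)`` rows of the table, order preserved."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return PairTable(rows=pt.rows[:t], n_features=pt.n_features,
                     feature_names=pt.feature_names, meta=dict(pt.meta),
                     check_sorted=pt.check_sorted)
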