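"""Original (unmodified) selection algorithms used as baselines.

Four univariate filters (chi-squared, gain ratio, ReliefF, FSDD), two
greedy wrapper searches (forward selection, backward elimination) driven by
cross-validated accuracy, and the mRMR mutual-information ranking.  All tie
breaks are by ascending feature index so every algorithm is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._eval import EvalConfig, cv_accuracy
from .core_io import Dataset, DiscretizationSpec, Ranking, discretize_codes
from .prefilter import mi_score

__all__ = [
    "SelectionResult",
    "Step",
    "chi_squared_rank",
    "gain_ratio_rank",
    "relief_rank",
    "fsdd_rank",
    "eval_subset",
    "forward_search",
    "backward_elimination",
    "mrmr_rank",
]


@dataclass(frozen=True)
class Step:
    """One accepted move of a subset search."""

    action: str                 # "add" or "remove"
    features: tuple[int, ...]
    accuracy: float


@dataclass
class SelectionResult:
    """Chosen feature indices (in selection order) plus the search trace."""

    chosen: list[int]
    trace: list[Step] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.chosen)) != len(self.chosen):
            raise ValueError("chosen contains duplicate features")

    @property
    def accuracy(self) -> float:
        return self.trace[-1].accuracy if self.trace else 0.0


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _contingency(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    nf, nc = codes.max() + 1, y.max() + 1
    return np.bincount(codes * nc + y, minlength=nf * nc).reshape(nf, nc)


def chi_squared_rank(ds: Dataset,
                     disc: DiscretizationSpec | None = None) -> Ranking:
    """Pearson chi-squared statistic of each binned feature against the class.

    No continuity correction; bins or classes with zero marginal count drop
    out of the statistic (their expected counts are zero).
    """
    disc = disc or DiscretizationSpec()
    codes = discretize_codes(ds, disc)
    y = ds.label_codes()
    scores = []
    for f in range(ds.n_features):
        obs = _contingency(codes[:, f], y)
        obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        scores.append(float(((obs - exp) ** 2 / exp).sum()))
    return Ranking.from_scores(scores)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def gain_ratio_rank(ds: Dataset,
                    disc: DiscretizationSpec | None = None) -> Ranking:
    """Information gain of the binned feature divided by its intrinsic value.

    ``GR = [H(C) - H(C|F)] / H(F)`` with base-2 logs; a feature with zero
    entropy (constant after binning) scores 0 by convention.
    """
    disc = disc or DiscretizationSpec()
    codes = discretize_codes(ds, disc)
    y = ds.label_codes()
    hc = _entropy(np.bincount(y))
    scores = []
    for f in range(ds.n_features):
        joint = _contingency(codes[:, f], y)
        pf = joint.sum(axis=1)
        hf = _entropy(pf)
        if hf == 0.0:
            scores.append(0.0)
            continue
        hc_given_f = sum(
            (pf[b] / pf.sum()) * _entropy(joint[b]) for b in range(len(pf))
            if pf[b] > 0
        )
        scores.append((hc - hc_given_f) / hf)
    return Ranking.from_scores(scores)


def relief_rank(ds: Dataset, k_neighbors: int = 3) -> Ranking:
    """Deterministic ReliefF weights over all instances.

    For every instance, the ``k`` nearest hits (same class) and ``k``
    nearest misses per other class are found under Manhattan distance on
    range-scaled values; the weight of feature ``f`` accumulates
    miss-differences (weighted by the class prior renormalized over the
    other classes) minus hit-differences, averaged over ``n * k``.  Features
    that separate classes get positive weight; constants get 0.
    """
    n, m = ds.n_samples, ds.n_features
    y = ds.label_codes()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() <= k_neighbors:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small} has {counts.min()} members; ReliefF with "
            f"k={k_neighbors} needs more than k per class"
        )
    rng_span = ds.values.max(axis=0) - ds.values.min(axis=0)
    scale = np.where(rng_span > 0, rng_span, 1.0)
    x = ds.values / scale
    priors = counts / n
    dist = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    w = np.zeros(m)
    for i in range(n):
        order = np.lexsort((np.arange(n), dist[i]))  # distance, then index
        same = y[order] == y[i]
        hits = order[same][:k_neighbors]
        w -= np.abs(x[i] - x[hits]).sum(axis=0) / (n * k_neighbors)
        for c in classes:
            if c == y[i]:
                continue
            misses = order[y[order] == c][:k_neighbors]
            wc = priors[c] / (1.0 - priors[y[i]])
            w += wc * np.abs(x[i] - x[misses]).sum(axis=0) / (n * k_neighbors)
    return Ranking.from_scores(w)


def fsdd_rank(ds: Dataset, beta: float = 2.0) -> Ranking:
    """Distance-discriminant filter: between-class spread minus ``beta``
    times within-class variance, computed on z-normalized values.

    ``J = sum_c p_c (mu_c - mu)^2 - beta * sum_c p_c sigma_c^2`` with class
    priors ``p_c``; z-normalization makes J invariant to affine rescaling of
    the raw feature.  A constant feature scores 0.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    y = ds.label_codes()
    classes, counts = np.unique(y, return_counts=True)
    priors = counts / ds.n_samples
    scores = []
    for f in range(ds.n_features):
        x = ds.values[:, f]
        sd = x.std()
        if sd == 0:
            scores.append(0.0)
            continue
        z = (x - x.mean()) / sd
        between = sum(
            p * z[y == c].mean() ** 2 for c, p in zip(classes, priors)
        )
        within = sum(
            p * z[y == c].var() for c, p in zip(classes, priors)
        )
        scores.append(float(between - beta * within))
    return Ranking.from_scores(scores)


# ---------------------------------------------------------------------------
# wrapper searches
# ---------------------------------------------------------------------------

def eval_subset(ds: Dataset, subset: Sequence[int],
                cfg: EvalConfig | None = None) -> float:
    """Cross-validated accuracy of a classifier on exactly those columns."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    for k in subset:
        if not 0 <= k < ds.n_features:
            raise IndexError(f"feature index {k} out of range")
    cfg = cfg or EvalConfig()
    return cv_accuracy(ds.values[:, subset], ds.label_codes(), cfg)


def forward_search(ds: Dataset, cfg: EvalConfig | None = None,
                   candidates: Sequence[int] | None = None,
                   max_steps: int | None = None) -> SelectionResult:
    """Greedy forward selection under a strict-improvement rule.

    Starting from the empty set (baseline accuracy 0), each step evaluates
    adding every unchosen feature and accepts the arg-max only if it
    strictly increases the current accuracy; the search stops otherwise.
    ``max_steps`` optionally caps the number of accepted steps.
    """
    cfg = cfg or EvalConfig()
    pool = list(candidates) if candidates is not None else list(range(ds.n_features))
    chosen: list[int] = []
    trace: list[Step] = []
    current = 0.0
    while max_steps is None or len(trace) < max_steps:
        best_x, best_acc = None, current
        for x in pool:
            if x in chosen:
                continue
            acc = eval_subset(ds, chosen + [x], cfg)
            if acc > best_acc:
                best_x, best_acc = x, acc
        if best_x is None:
            break
        chosen.append(best_x)
        trace.append(Step("add", (best_x,), best_acc))
        current = best_acc
    return SelectionResult(chosen, trace)


def backward_elimination(ds: Dataset, cfg: EvalConfig | None = None,
                         initial: Sequence[int] | None = None
                         ) -> SelectionResult:
    """Greedy backward elimination under a non-worsening rule.

    Starting from the full set (or ``initial``), each step removes the
    feature whose removal yields the highest accuracy, accepted while that
    accuracy is at least the current one; ties between removals break to the
    lowest feature index.  Stops when every removal strictly hurts or one
    feature remains.
    """
    cfg = cfg or EvalConfig()
    chosen = (list(initial) if initial is not None
              else list(range(ds.n_features)))
    if not chosen:
        raise ValueError("initial subset must be non-empty")
    current = eval_subset(ds, chosen, cfg)
    trace: list[Step] = [Step("start", tuple(chosen), current)]
    while len(chosen) > 1:
        best_x, best_acc = None, -1.0
        for x in chosen:
            acc = eval_subset(ds, [f for f in chosen if f != x], cfg)
            if acc > best_acc:
                best_x, best_acc = x, acc
        if best_acc < current:
            break
        chosen.remove(best_x)
        trace.append(Step("remove", (best_x,), best_acc))
        current = best_acc
    return SelectionResult(chosen, trace)


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def mrmr_rank(ds: Dataset, disc: DiscretizationSpec | None = None,
              m: int | None = None) -> Ranking:
    """Greedy mRMR (MID scheme) on binned codes.

    The first pick maximizes relevance ``I(F; C)``; each later pick
    maximizes ``I(x; C) - mean_{s in S} I(x; s)`` over the unchosen
    features.  There is no stopping rule: exactly ``m`` features are
    returned in pick order (all features when ``m`` is omitted).
    """
    disc = disc or DiscretizationSpec()
    if m is None:
        m = ds.n_features
    if not 1 <= m <= ds.n_features:
        raise ValueError(f"m={m} out of range for {ds.n_features} features")
    codes = discretize_codes(ds, disc)
    rel = np.array([mi_score(codes[:, f], ds.labels)
                    for f in range(ds.n_features)])
    mi_cache: dict[tuple[int, int], float] = {}

    def mi_ff(a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = mi_score(codes[:, key[0]], codes[:, key[1]])
        return mi_cache[key]

    chosen = [int(np.lexsort((np.arange(len(rel)), -rel))[0])]
    while len(chosen) < m:
        best_x, best_score = None, -np.inf
        for x in range(ds.n_features):
            if x in chosen:
                continue
            red = sum(mi_ff(x, s) for s in chosen) / len(chosen)
            score = rel[x] - red
            if score > best_score:
                best_x, best_score = x, score
        chosen.append(best_x)
    return Ranking(order=np.array(chosen), scores=None)
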