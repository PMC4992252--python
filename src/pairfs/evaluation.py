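"""Reporting evaluators: LOOCV accuracy of selected subsets and the
count-by-method accuracy profile table.

Leave-one-out cross-validation is the canonical protocol: each sample is
predicted by a model trained on all others, so every reported accuracy is a
multiple of ``1 / n_samples``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from ._eval import EvalConfig
from .base_selectors import eval_subset
from .core_io import Dataset, Ranking

__all__ = ["loocv_accuracy", "accuracy_profile", "default_eval_configs"]


def default_eval_configs() -> dict[str, EvalConfig]:
    """The standard reporting pair: 3-NN and a linear SVM, both LOOCV."""
    return {
        "knn": EvalConfig(classifier="knn", params={"k": 3}, cv="loocv"),
        "svm_linear": EvalConfig(classifier="svm_linear", cv="loocv"),
    }


def loocv_accuracy(ds: Dataset, subset: Sequence[int],
                   cfg: EvalConfig | None = None) -> float:
    """LOOCV accuracy of a classifier on exactly the given columns."""
    cfg = cfg or EvalConfig()
    if cfg.cv != "loocv":
        cfg = EvalConfig(classifier=cfg.classifier, params=cfg.params,
                         cv="loocv", seed=cfg.seed)
    return eval_subset(ds, subset, cfg)


def accuracy_profile(ds: Dataset, rankings: Mapping[str, Ranking],
                     counts: Sequence[int],
                     classifiers: Mapping[str, EvalConfig] | None = None
                     ) -> pd.DataFrame:
    """Accuracy of each ranking's first ``count`` features, per classifier.

    Returns a table with one row per count plus a ``MAX`` row per classifier
    (the column-wise maximum over the count rows); columns are
    ``(classifier, ranking name)``.  The computation is pure: identical
    inputs give identical tables.
    """
    classifiers = classifiers or default_eval_configs()
    counts = list(counts)
    for name, rk in rankings.items():
        for c in counts:
            if not 1 <= c <= len(rk):
                raise ValueError(
                    f"count {c} exceeds ranking {name!r} of length {len(rk)}"
                )
    cols = pd.MultiIndex.from_tuples(
        [(clf, rk) for clf in classifiers for rk in rankings],
        names=["classifier", "ranking"],
    )
    rows = []
    for c in counts:
        row = []
        for clf_name, cfg in classifiers.items():
            for rk_name, rk in rankings.items():
                row.append(loocv_accuracy(ds, rk.top(c), cfg))
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(counts, name="n_features"),
                      columns=cols)
    col_max = df.loc[counts].max(axis=0)
    for clf_name in classifiers:
        row = pd.Series(float("nan"), index=df.columns)
        for rk_name in rankings:
            row[(clf_name, rk_name)] = col_max[(clf_name, rk_name)]
        df.loc[f"MAX {clf_name}"] = row
    return df
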