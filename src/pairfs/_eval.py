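"""Cross-validated accuracy engine shared by the pair table, the wrapper
searches and the reporting evaluator.

Two code paths produce identical contracts:

* a generic fold loop (any registered classifier, LOOCV or stratified
  k-fold) with per-fold standardization for scale-sensitive classifiers;
* a closed-form LOOCV path for KNN that exploits the fact that after
  training-fold standardization only the per-fold scale enters the
  neighbour distances, so all folds can be evaluated from one pairwise
  squared-difference tensor.

KNN neighbour rule: every training point tied with the k-th smallest
distance joins the vote; vote ties break to the lowest class label.  This
makes the degenerate all-constant case behave like a training-set majority
vote, the natural limit of KNN under total distance ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = ["EvalConfig", "cv_accuracy", "CLASSIFIERS"]

CLASSIFIERS = ("svm_linear", "knn", "random_forest", "naive_bayes")

#: classifiers whose decision depends on feature scale; standardized with
#: training-fold mean/std only
_SCALE_SENSITIVE = ("svm_linear", "knn")


@dataclass(frozen=True)
class EvalConfig:
    """How a feature subset is scored: classifier, its parameters, and CV.

    ``cv`` is ``"loocv"`` (the default, matching the reporting protocol) or
    ``"stratified_kfold"`` with ``n_folds`` folds (a fast mode for large
    feature counts; tables record which was used).  ``seed`` feeds the only
    stochastic classifier (random forest); everything else is deterministic.
    """

    classifier: str = "svm_linear"
    params: Mapping[str, Any] = field(default_factory=dict)
    cv: str = "loocv"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; "
                f"choose from {CLASSIFIERS}"
            )
        if self.cv not in ("loocv", "stratified_kfold"):
            raise ValueError(f"unknown cv scheme {self.cv!r}")
        if self.cv == "stratified_kfold" and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        object.__setattr__(self, "params", dict(self.params))

    def describe(self) -> dict[str, str]:
        cv = "loocv" if self.cv == "loocv" else f"stratified_kfold({self.n_folds})"
        d = {"classifier": self.classifier, "cv": cv}
        for k, v in sorted(self.params.items()):
            d[f"param_{k}"] = str(v)
        return d


def _make_classifier(cfg: EvalConfig):
    p = cfg.params
    if cfg.classifier == "svm_linear":
        from sklearn.svm import SVC

        return SVC(kernel="linear", C=float(p.get("C", 1.0)))
    if cfg.classifier == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=int(p.get("n_estimators", 100)),
            random_state=cfg.seed,
        )
    if cfg.classifier == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    raise AssertionError(cfg.classifier)


def _knn_predict(train_x: np.ndarray, train_y: np.ndarray,
                 test_x: np.ndarray, k: int) -> np.ndarray:
    """KNN with the tie rule documented in the module docstring.

    Labels must be integer codes with 0 = lowest class label.
    """
    d2 = ((test_x[:, None, :] - train_x[None, :, :]) ** 2).sum(axis=2)
    n_classes = int(train_y.max()) + 1
    k = min(k, train_x.shape[0])
    preds = np.empty(test_x.shape[0], dtype=int)
    for t in range(test_x.shape[0]):
        row = d2[t]
        kth = np.partition(row, k - 1)[k - 1]
        votes = np.bincount(train_y[row <= kth], minlength=n_classes)
        preds[t] = int(np.argmax(votes))  # argmax -> lowest label on ties
    return preds


def _loocv_knn_fast(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Exact LOOCV accuracy for KNN with per-fold standardization.

    Standardizing with training-fold statistics shifts every point by the
    same amount per feature, so only the per-fold scale 1/sigma enters the
    test-to-train distances; those scales come from leave-one-out moment
    updates and all folds share one squared-difference tensor.
    """
    n, m = x.shape
    s = x.sum(axis=0)
    q = (x ** 2).sum(axis=0)
    nt = n - 1
    mean_lo = (s[None, :] - x) / nt                      # fold i training mean
    var_lo = (q[None, :] - x ** 2) / nt - mean_lo ** 2   # ddof=0 variance
    inv_var = np.where(var_lo > 1e-24, 1.0 / np.maximum(var_lo, 1e-24), 1.0)
    n_classes = int(y.max()) + 1
    k = min(k, nt)
    # per-feature squared diffs, weighted per test row by its fold scale
    d = np.zeros((n, n))
    for f in range(m):
        diff2 = (x[:, f][:, None] - x[:, f][None, :]) ** 2
        d += diff2 * inv_var[:, f][:, None]
    np.fill_diagonal(d, np.inf)
    correct = 0
    for i in range(n):
        row = d[i]
        kth = np.partition(row, k - 1)[k - 1]
        votes = np.bincount(y[row <= kth], minlength=n_classes)
        if int(np.argmax(votes)) == y[i]:
            correct += 1
    return correct / n


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def cv_accuracy(x: np.ndarray, y_codes: np.ndarray, cfg: EvalConfig) -> float:
    """Cross-validated accuracy of ``cfg`` on the given columns.

    ``y_codes`` are integer class codes (0 = lowest label).  LOOCV requires
    every class to have at least 2 members.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y_codes, dtype=int)
    n = x.shape[0]
    counts = np.bincount(y)
    if cfg.cv == "loocv" and counts[counts > 0].min() < 2:
        raise ValueError("LOOCV requires every class to have >= 2 samples")

    if cfg.classifier == "knn":
        k = int(cfg.params.get("k", 3))
        if cfg.cv == "loocv":
            return _loocv_knn_fast(x, y, k)
        correct = 0
        for tr, te in _kfold_indices(y, cfg.n_folds):
            xt, xe = _standardize(x[tr], x[te])
            preds = _knn_predict(xt, y[tr], xe, k)
            correct += int((preds == y[te]).sum())
        return correct / n

    correct = 0
    folds = (
        ((np.delete(np.arange(n), i), np.array([i])) for i in range(n))
        if cfg.cv == "loocv"
        else _kfold_indices(y, cfg.n_folds)
    )
    for tr, te in folds:
        xt, xe = x[tr], x[te]
        if cfg.classifier in _SCALE_SENSITIVE:
            xt, xe = _standardize(xt, xe)
        clf = _make_classifier(cfg)
        if len(np.unique(y[tr])) < 2:
            # degenerate fold: predict the only training class
            preds = np.full(len(te), y[tr][0])
        else:
            clf.fit(xt, y[tr])
            preds = clf.predict(xe)
        correct += int((preds == y[te]).sum())
    return correct / n


def _kfold_indices(y: np.ndarray, n_folds: int):
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    yield from skf.split(np.zeros(len(y)), y)
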