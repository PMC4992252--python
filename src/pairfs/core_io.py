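"""Core data model: labeled feature matrices, discretization, and text I/O.

A :class:`Dataset` is the in-memory form of a microarray-style table:
continuous expression values for ``n_samples x n_features``, one class label
per sample, and a unique name per feature.  Features are addressed internally
by 0-based column index; files and reports always show feature names.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "Ranking",
    "DiscretizationSpec",
    "load_dataset",
    "save_dataset",
    "discretize",
    "write_pair_table",
    "read_pair_table",
]


class DatasetError(ValueError):
    """Raised when a feature matrix violates the data-model invariants."""


@dataclass
class Dataset:
    """Labeled sample-by-feature matrix.

    Parameters
    ----------
    values:
        Real-valued array of shape ``(n_samples, n_features)``.
    labels:
        Class label per sample (any hashable; stored as a numpy array).
    feature_names:
        Unique name per feature, aligned with the columns of ``values``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = [str(n) for n in self.feature_names]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D samples x features array")
        n_samples, n_features = self.values.shape
        if len(self.labels) != n_samples:
            raise DatasetError(
                f"labels length {len(self.labels)} does not match "
                f"{n_samples} rows of values"
            )
        if len(self.feature_names) != n_features:
            raise DatasetError(
                f"{len(self.feature_names)} feature names for "
                f"{n_features} columns"
            )
        if len(set(self.feature_names)) != n_features:
            raise DatasetError("feature names must be unique")
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise DatasetError(
                f"missing value at sample {r}, feature {self.feature_names[c]!r}"
            )
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2:
            raise DatasetError("fewer than 2 classes")
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise DatasetError(
                f"class {small!r} has fewer than 2 samples"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def label_codes(self) -> np.ndarray:
        """Labels as integer codes, 0 = lowest label in sorted order."""
        _, codes = np.unique(self.labels, return_inverse=True)
        return codes

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """New Dataset restricted to the given feature columns (in order)."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            self.values[:, idx],
            self.labels.copy(),
            [self.feature_names[i] for i in idx],
        )

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[label_column] = self.labels
        return df


@dataclass
class Ranking:
    """Ordered feature indices, optionally with per-feature scores.

    When ``scores`` is present the order must be score-descending with ties
    broken by ascending feature index; :meth:`from_scores` builds a conforming
    ranking from raw scores.  Derived orders (e.g. mRMR pick order or a
    pair-table reordering) carry ``scores=None``.
    """

    order: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        if len(set(self.order.tolist())) != len(self.order):
            raise ValueError("ranking order contains duplicate feature indices")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if len(self.scores) != len(self.order):
                raise ValueError("scores not aligned with order")
            if len(self.order) > 1:
                dec = np.diff(self.scores) <= 0
                if not dec.all():
                    raise ValueError("order is not sorted by descending score")
                tied = np.diff(self.scores) == 0
                bad = tied & (np.diff(self.order) < 0)
                if bad.any():
                    raise ValueError("score ties must break by ascending index")

    @classmethod
    def from_scores(cls, scores: Sequence[float]) -> "Ranking":
        """Rank all features by score, descending; ties by ascending index."""
        s = np.asarray(scores, dtype=float)
        order = np.lexsort((np.arange(len(s)), -s))
        return cls(order=order, scores=s[order])

    def top(self, m: int) -> np.ndarray:
        return self.order[:m]

    def __len__(self) -> int:
        return len(self.order)


@dataclass(frozen=True)
class DiscretizationSpec:
    """Binning recipe used by entropy-based scores on continuous data.

    ``equal_frequency`` places cut points at empirical quantiles (order
    statistics, so the codes are invariant to any strictly monotone
    transform); ``equal_width`` splits the observed range into equal
    intervals.  Upper bin edges are inclusive.
    """

    n_bins: int = 5
    strategy: str = "equal_frequency"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.strategy not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def discretize_feature(x: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    """Integer codes ``0..n_bins-1`` for one feature; constants map to 0."""
    x = np.asarray(x, dtype=float)
    if x.min() == x.max():
        return np.zeros(len(x), dtype=int)
    if spec.strategy == "equal_frequency":
        q = np.linspace(0, 1, spec.n_bins + 1)[1:-1]
        # interpolated edges fall between order statistics (or on one), so
        # the induced partition commutes with strictly monotone transforms
        edges = np.unique(np.quantile(x, q))
        return np.digitize(x, edges, right=False)
    edges = np.unique(np.linspace(x.min(), x.max(), spec.n_bins + 1)[1:-1])
    return np.digitize(x, edges, right=True)


def discretize(ds: Dataset, spec: DiscretizationSpec) -> Dataset:
    """Bin every feature independently to integer codes (as floats)."""
    codes = np.column_stack(
        [discretize_feature(ds.values[:, f], spec) for f in range(ds.n_features)]
    )
    return Dataset(codes.astype(float), ds.labels.copy(), list(ds.feature_names))


def discretize_codes(ds: Dataset, spec: DiscretizationSpec) -> np.ndarray:
    """Binned integer codes, shape ``(n_samples, n_features)``."""
    return np.column_stack(
        [discretize_feature(ds.values[:, f], spec) for f in range(ds.n_features)]
    )


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def load_dataset(path: str | Path, label_column: str = "class",
                 delimiter: str = ",") -> Dataset:
    """Read a delimited text table with a header row and one label column.

    Every non-label column must be numeric with no missing cells; the label
    column is removed from the value matrix and feature order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    df = pd.read_csv(path, sep=delimiter)
    if label_column not in df.columns:
        raise DatasetError(
            f"label column {label_column!r} not found in {path.name} "
            f"(columns: {', '.join(map(str, df.columns[:8]))}...)"
        )
    labels = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        if feats[col].isna().any():
            row = int(feats[col].isna().idxmax())
            raise DatasetError(
                f"missing value in column {col!r}, row {row}"
            )
        if not np.issubdtype(feats[col].dtype, np.number):
            raise DatasetError(f"non-numeric value in feature column {col!r}")
    return Dataset(feats.to_numpy(dtype=float), labels,
                   [str(c) for c in feats.columns])


def save_dataset(ds: Dataset, path: str | Path, label_column: str = "class",
                 delimiter: str = ",") -> None:
    ds.to_frame(label_column).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# pair-table I/O (format: feature names, accuracy with 6 decimals)
# ---------------------------------------------------------------------------

PAIR_TABLE_HEADER = "feature_i,feature_j,accuracy"


def write_pair_table(pt, path: str | Path) -> None:
    """Write a pair table as CSV, feature names and 6-decimal accuracies.

    A ``# features:`` comment line records the full index -> name mapping so
    that a read round-trips losslessly; evaluator metadata is recorded so
    cached tables built under different settings are never silently mixed.
    """
    path = Path(path)
    names = pt.feature_names or [f"f{i}" for i in range(pt.n_features)]
    with path.open("w") as fh:
        fh.write(f"# features: {','.join(names)}\n")
        if pt.meta:
            meta = "; ".join(f"{k}={v}" for k, v in sorted(pt.meta.items()))
            fh.write(f"# eval: {meta}\n")
        fh.write(PAIR_TABLE_HEADER + "\n")
        for i, j, v in pt.rows:
            fh.write(f"{names[i]},{names[j]},{v:.6f}\n")


def read_pair_table(path: str | Path):
    """Read a pair table written by :func:`write_pair_table`.

    Hand-made files without the ``# features:`` line are accepted: indices
    are then assigned by first occurrence of each name.  Duplicate unordered
    pairs and out-of-range indices are errors.
    """
    from .pairtable import PairTable  # local import avoids a cycle

    path = Path(path)
    names: list[str] | None = None
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, float]] = []
    name_to_idx: dict[str, int] = {}
    seen: set[tuple[int, int]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# features:"):
                names = line.split(":", 1)[1].strip().split(",")
                name_to_idx = {n: k for k, n in enumerate(names)}
                continue
            if line.startswith("# eval:"):
                for part in line.split(":", 1)[1].split(";"):
                    if "=" in part:
                        k, v = part.split("=", 1)
                        meta[k.strip()] = v.strip()
                continue
            if line.startswith("#") or line == PAIR_TABLE_HEADER:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"malformed pair-table row at line {lineno}: {line!r}")
            a, b, vs = parts
            try:
                v = float(vs)
            except ValueError:
                raise ValueError(
                    f"malformed accuracy at line {lineno}: {vs!r}"
                ) from None
            for n in (a, b):
                if n not in name_to_idx:
                    if names is not None:
                        raise ValueError(
                            f"feature {n!r} at line {lineno} not in table header"
                        )
                    name_to_idx[n] = len(name_to_idx)
            i, j = name_to_idx[a], name_to_idx[b]
            if i == j:
                raise ValueError(f"self-pair at line {lineno}: {a!r}")
            if i > j:
                i, j = j, i
            if (i, j) in seen:
                raise ValueError(f"duplicate unordered pair {a!r},{b!r} at line {lineno}")
            seen.add((i, j))
            rows.append((i, j, v))
    if names is None:
        names = [n for n, _ in sorted(name_to_idx.items(), key=lambda kv: kv[1])]
    for i, j, _ in rows:
        if j >= len(names):
            raise ValueError(f"feature index {j} out of range for {len(names)} features")
    return PairTable(rows=rows, n_features=len(names), feature_names=names,
                     meta=meta, check_sorted=False)
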