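"""Dataset readers/writers: sparse LIBSVM text and dense CSV with header.

LIBSVM lines look like ``label idx:val idx:val ...`` with 1-based feature
indices on disk; internally features are 0-based and labelled ``f<k>`` by
their 1-based on-disk index.  Class labels ``{-1, +1}`` or ``{0, 1}`` are
normalized to ``{0, 1}``.  Sparse matrices are kept sparse; the selection
engine densifies one block at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "DatasetHandle",
    "read_libsvm",
    "write_libsvm",
    "read_dense_csv",
    "write_dense_csv",
]


@dataclass
class DatasetHandle:
    """In-memory dataset: feature matrix, binary target, labels."""

    X: np.ndarray | sp.spmatrix
    y: np.ndarray
    feature_labels: list[str]
    source_format: str

    def __post_init__(self) -> None:
        vals = np.unique(self.y)
        if not np.all(np.isin(vals, [0.0, 1.0])):
            raise ValueError(f"target must be binary 0/1, found values {vals}")
        if self.X.shape[0] != self.y.size:
            raise ValueError("matrix rows and target length differ")
        if len(set(self.feature_labels)) != len(self.feature_labels):
            raise ValueError("feature labels must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


def _normalize_labels(raw: np.ndarray) -> np.ndarray:
    vals = set(np.unique(raw).tolist())
    if vals <= {0.0, 1.0}:
        return raw.astype(np.float64)
    if vals <= {-1.0, 1.0}:
        return ((raw + 1.0) / 2.0).astype(np.float64)
    raise ValueError(f"non-binary class labels {sorted(vals)}; expected 0/1 or -1/+1")


def read_libsvm(path, n_features: int | None = None) -> DatasetHandle:
    """Read a sparse LIBSVM text file.

    Indices are 1-based on disk and mapped to 0-based columns labelled by
    their on-disk index (``f1`` is column 0).  Raises a ``ValueError``
    naming the offending line on malformed input.
    """
    from sklearn.datasets import load_svmlight_file

    try:
        X, raw = load_svmlight_file(str(path), n_features=n_features)
    except ValueError as exc:
        lineno = _find_bad_line(path)
        raise ValueError(f"malformed LIBSVM input at {path}:{lineno}: {exc}") from exc
    y = _normalize_labels(np.asarray(raw, dtype=float))
    labels = [f"f{j + 1}" for j in range(X.shape[1])]
    return DatasetHandle(X=X.tocsr(), y=y, feature_labels=labels, source_format="libsvm")


def _find_bad_line(path) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            for tok in line.split()[1:]:
                parts = tok.split(":")
                if len(parts) != 2:
                    return lineno
                try:
                    int(parts[0])
                    float(parts[1])
                except ValueError:
                    return lineno
            first = line.split(maxsplit=1)
            if first:
                try:
                    float(first[0])
                except ValueError:
                    return lineno
    return -1


def write_libsvm(handle: DatasetHandle, path) -> None:
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(handle.X, handle.y, str(path), zero_based=False)


def read_dense_csv(path, target_column: str) -> DatasetHandle:
    """Read a dense CSV with a header row; extract and validate the binary target."""
    df = pd.read_csv(path)
    if target_column not in df.columns:
        raise KeyError(f"target column {target_column!r} not found in {path}")
    try:
        values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        bad = _find_bad_cell(df)
        raise ValueError(f"non-numeric cell at row {bad[0]}, column {bad[1]!r} in {path}") from exc
    cols = list(df.columns)
    t = cols.index(target_column)
    y = _normalize_labels(values[:, t])
    feats = [c for c in cols if c != target_column]
    X = np.delete(values, t, axis=1)
    return DatasetHandle(X=X, y=y, feature_labels=feats, source_format="csv")


def _find_bad_cell(df: pd.DataFrame):
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return int(np.flatnonzero(bad)[0]), col
    return -1, "?"


def write_dense_csv(handle: DatasetHandle, path, target_column: str = "T") -> None:
    X = handle.X.toarray() if sp.issparse(handle.X) else np.asarray(handle.X)
    df = pd.DataFrame(X, columns=handle.feature_labels)
    df[target_column] = handle.y.astype(int)
    df.to_csv(path, index=False)
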