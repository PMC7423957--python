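"""Multi-view dataset container, delimited-text I/O and per-view preprocessing.

A *view* is one feature matrix (samples x features) describing the same
cohort — e.g. gene expression, miRNA expression and DNA methylation for the
same patients.  Views may be *incomplete*: a sample can be missing from some
views, as long as it occurs in at least one.  Rows of absent samples are kept
as zero-filled placeholders so that every view shares the same row universe
and row order; a boolean presence mask records which rows are real.

All preprocessing statistics (variance ranking, normalization) are computed
over present rows only, since the zero placeholders would otherwise bias the
moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MultiViewDataset",
    "ConcatenatedMatrix",
    "read_view",
    "write_view",
    "read_labels",
    "align_views",
    "variance_rank_select",
    "normalize_features",
    "concatenate_views",
]


@dataclass
class MultiViewDataset:
    """Aligned multi-view data with a per-view presence mask.

    Attributes
    ----------
    views : list of ndarray, each (n_samples, d_v)
        One matrix per view.  Rows of samples absent from a view are zero.
    sample_ids : list of str, length n_samples
        Shared row universe, identical order across views.
    presence : ndarray of bool, (n_samples, n_views)
        ``presence[i, v]`` is True iff sample *i* occurs in view *v*.
    labels : ndarray of int or None
        Optional ground-truth labels for evaluation.
    """

    views: list[np.ndarray]
    sample_ids: list[str]
    presence: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.views = [np.asarray(v, dtype=float) for v in self.views]
        self.presence = np.asarray(self.presence, dtype=bool)
        n = len(self.sample_ids)
        m = len(self.views)
        if self.presence.shape != (n, m):
            raise ValueError(
                f"presence shape {self.presence.shape} != (n={n}, m={m})"
            )
        for v, X in enumerate(self.views):
            if X.ndim != 2 or X.shape[0] != n:
                raise ValueError(f"view {v} has shape {X.shape}, expected ({n}, d_v)")
            if X.shape[1] < 1:
                raise ValueError(f"view {v} has no features")
            present = self.presence[:, v]
            if not np.isfinite(X[present]).all():
                raise ValueError(f"view {v} contains non-finite values in present rows")
        if not self.presence.any(axis=1).all():
            missing = [self.sample_ids[i] for i in np.where(~self.presence.any(axis=1))[0]]
            raise ValueError(f"samples absent from every view: {missing}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must equal n_samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def is_complete(self) -> bool:
        return bool(self.presence.all())


@dataclass
class ConcatenatedMatrix:
    """Horizontal concatenation of all views; absent blocks are exactly zero."""

    data: np.ndarray
    block_offsets: list[tuple[int, int]] = field(default_factory=list)

    def view_block(self, v: int) -> np.ndarray:
        start, stop = self.block_offsets[v]
        return self.data[:, start:stop]


def read_view(path, delimiter: str = "\t") -> tuple[np.ndarray, list[str]]:
    """Read one view from a delimited table.

    First column holds sample ids, the header row holds feature names.
    Returns ``(matrix, sample_ids)`` with rows in file order.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed table: {exc}") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    ids = [str(i) for i in df.index]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-numeric or non-finite cell at row {ids[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return values, ids


def write_view(path, X: np.ndarray, sample_ids: list[str],
               feature_names: list[str] | None = None,
               delimiter: str = "\t") -> None:
    """Write a view in the dialect :func:`read_view` reads (round-trip safe)."""
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, index=sample_ids, columns=feature_names)
    # repr round-trips doubles exactly
    df.to_csv(path, sep=delimiter, index_label="sample", float_format="%.17g")


def read_labels(path, delimiter: str = "\t") -> dict[str, int]:
    """Read a two-column (id, label) file into a mapping."""
    df = pd.read_csv(path, sep=delimiter, header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, label)")
    ids = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1]
    codes = pd.factorize(labels)[0] if labels.dtype == object else labels.astype(int)
    return dict(zip(ids, np.asarray(codes, dtype=int)))


def align_views(raw_views: list[tuple[np.ndarray, list[str]]]) -> MultiViewDataset:
    """Align per-view matrices onto the union of their sample ids.

    The row universe is ordered by first appearance across views (view order
    first, file order within a view).  Rows absent from a view become
    zero-filled placeholders flagged absent in the presence mask.
    """
    if not raw_views:
        raise ValueError("need at least one view")
    universe: list[str] = []
    seen: set[str] = set()
    for v, (_, ids) in enumerate(raw_views):
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in view {v}: {dups}")
        for sid in ids:
            if sid not in seen:
                seen.add(sid)
                universe.append(sid)
    n, m = len(universe), len(raw_views)
    pos = {sid: i for i, sid in enumerate(universe)}
    presence = np.zeros((n, m), dtype=bool)
    views = []
    for v, (X, ids) in enumerate(raw_views):
        X = np.asarray(X, dtype=float)
        full = np.zeros((n, X.shape[1]))
        rows = [pos[sid] for sid in ids]
        full[rows] = X
        presence[rows, v] = True
        views.append(full)
    return MultiViewDataset(views=views, sample_ids=universe, presence=presence)


def variance_rank_select(X: np.ndarray, k_features: int | None = None,
                         fraction: float | None = None,
                         present: np.ndarray | None = None) -> np.ndarray:
    """Keep the columns with the highest variance.

    Either an absolute count ``k_features`` or a ``fraction`` of the columns
    may be given (the fractional form mirrors percentage-based selection used
    for low-dimensional views such as miRNA).  Variance is the population
    (1/n) estimator over present rows; ties break toward the lower column
    index and the surviving columns keep their original order.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if k_features is None:
        if fraction is None:
            raise ValueError("give k_features or fraction")
        k_features = max(1, int(round(fraction * d)))
    if k_features <= 0:
        raise ValueError(f"k_features must be positive, got {k_features}")
    if k_features > d:
        raise ValueError(f"k_features={k_features} exceeds feature count {d}")
    rows = X if present is None else X[np.asarray(present, dtype=bool)]
    var = rows.var(axis=0)  # population estimator
    order = np.lexsort((np.arange(d), -var))  # stable: high var first, low index on ties
    keep = np.sort(order[:k_features])
    return X[:, keep]


def normalize_features(X: np.ndarray, mode: str = "zscore",
                       present: np.ndarray | None = None) -> np.ndarray:
    """Column-wise normalization computed over present rows only.

    ``zscore`` centres to mean 0, population sd 1 (constant columns become
    all zero); ``minmax`` maps to [0, 1]; ``none`` is the identity.  Absent
    rows stay exactly zero.
    """
    X = np.asarray(X, dtype=float)
    if mode == "none":
        return X.copy()
    mask = np.ones(X.shape[0], dtype=bool) if present is None else np.asarray(present, bool)
    rows = X[mask]
    out = np.zeros_like(X)
    if mode == "zscore":
        mu = rows.mean(axis=0)
        sd = rows.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        # constant columns: rows - mu is identically 0, so they come out all-zero
        out[mask] = (rows - mu) / sd_safe
    elif mode == "minmax":
        lo = rows.min(axis=0)
        rng = rows.max(axis=0) - lo
        rng_safe = np.where(rng > 0, rng, 1.0)
        out[mask] = (rows - lo) / rng_safe
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out


def concatenate_views(ds: MultiViewDataset) -> ConcatenatedMatrix:
    """Concatenate views horizontally; missing features stay zero.

    Absent samples contribute zero blocks in the views they miss, which is
    the convention used to build the input of the autoencoder initializer.
    """
    offsets = []
    start = 0
    for X in ds.views:
        offsets.append((start, start + X.shape[1]))
        start += X.shape[1]
    data = np.hstack(ds.views)
    # absent rows must be exactly zero even if caller mutated them
    for v, X in enumerate(ds.views):
        absent = ~ds.presence[:, v]
        if absent.any() and np.any(X[absent] != 0):
            warnings.warn(f"view {v}: nonzero entries in absent rows were zeroed")
            a, b = offsets[v]
            data[absent, a:b] = 0.0
    return ConcatenatedMatrix(data=data, block_offsets=offsets)
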