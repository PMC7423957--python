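"""External cluster-validity metrics and SNR-based marker scoring.

NMI uses the arithmetic normalization 2 I(C;E) / (H(C) + H(E)); ARI is the
standard permutation-model adjusted Rand index.  Macro F1 and accuracy are
computed after mapping clusters to classes by the optimal one-to-one
assignment (Hungarian algorithm) that maximizes total agreement.

Marker scoring follows the one-vs-rest signal-to-noise ratio
SNR = (mu1 - mu2) / (sd1 + sd2) * 100 per gene, from which the top
up-regulated (highest SNR) and down-regulated (lowest SNR) genes per class
are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (adjusted_rand_score, f1_score,
                             normalized_mutual_info_score)

__all__ = [
    "nmi",
    "ari",
    "mapped_f1_accuracy",
    "snr_scores",
    "select_markers",
    "marker_table",
]


def _check_pair(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth).ravel()
    p = np.asarray(predicted).ravel()
    if t.shape != p.shape:
        raise ValueError(f"partition lengths differ: {t.shape[0]} vs {p.shape[0]}")
    if t.size == 0:
        raise ValueError("empty partitions")
    return t, p


def nmi(truth, predicted) -> float:
    """Normalized mutual information, 2 I / (H(C) + H(E)), in [0, 1].

    When both partitions are single-class (both entropies zero) the
    partitions are trivially identical and the value is defined as 1.
    """
    t, p = _check_pair(truth, predicted)
    if len(np.unique(t)) == 1 and len(np.unique(p)) == 1:
        return 1.0
    return float(normalized_mutual_info_score(t, p, average_method="arithmetic"))


def ari(truth, predicted) -> float:
    """Adjusted Rand index (pair counting, permutation-model expectation)."""
    t, p = _check_pair(truth, predicted)
    return float(adjusted_rand_score(t, p))


def mapped_f1_accuracy(truth, predicted) -> tuple[float, float]:
    """(macro F1, accuracy) after optimal one-to-one cluster-to-class mapping.

    Clusters left unmatched (more clusters than classes) map to a sentinel
    label and count as errors; macro F1 averages over the true classes.
    """
    t, p = _check_pair(truth, predicted)
    classes = np.unique(t)
    clusters = np.unique(p)
    # contingency: rows clusters, cols classes
    cont = np.zeros((clusters.size, classes.size), dtype=int)
    for ci, c in enumerate(clusters):
        for ki, k in enumerate(classes):
            cont[ci, ki] = int(np.sum((p == c) & (t == k)))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {clusters[r]: classes[c] for r, c in zip(rows, cols)}
    sentinel = classes.min() - 1
    mapped = np.array([mapping.get(c, sentinel) for c in p])
    accuracy = float(np.mean(mapped == t))
    macro_f1 = float(f1_score(t, mapped, labels=classes, average="macro",
                              zero_division=0))
    return macro_f1, accuracy


def snr_scores(expr: np.ndarray, class_mask: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise ratio, (mu1 - mu2) / (sd1 + sd2) * 100.

    ``expr`` is genes x samples; ``class_mask`` flags the in-class samples
    (one-vs-rest).  Standard deviations are population (1/n).  Genes whose
    denominator is zero get SNR 0 with a warning.
    """
    X = np.asarray(expr, dtype=float)
    mask = np.asarray(class_mask, dtype=bool).ravel()
    if X.shape[1] != mask.size:
        raise ValueError("class_mask length must equal the number of samples")
    if mask.all() or not mask.any():
        raise ValueError("both classes must be non-empty")
    mu1 = X[:, mask].mean(axis=1)
    mu2 = X[:, ~mask].mean(axis=1)
    sd1 = X[:, mask].std(axis=1)
    sd2 = X[:, ~mask].std(axis=1)
    denom = sd1 + sd2
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes have zero variance in both "
                      "classes; SNR set to 0")
    out = np.zeros(X.shape[0])
    nz = ~zero
    out[nz] = (mu1[nz] - mu2[nz]) / denom[nz] * 100.0
    return out


def select_markers(snr: np.ndarray, n_up: int = 5, n_down: int = 5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the top ``n_up`` (highest SNR) and bottom ``n_down`` genes.

    Ties break by gene order: the up set prefers earlier genes, the down set
    later ones, so fully tied scores yield the first ``n_up`` and the last
    ``n_down`` genes.  The two sets must not overlap:
    n_up + n_down <= number of genes.
    """
    s = np.asarray(snr, dtype=float).ravel()
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    if n_up + n_down > s.size:
        raise ValueError(f"n_up + n_down = {n_up + n_down} exceeds {s.size} genes")
    d = s.size
    desc = np.lexsort((np.arange(d), -s))    # high SNR first, low index on ties
    asc = np.lexsort((-np.arange(d), s))     # low SNR first, high index on ties
    up = np.sort(desc[:n_up])
    down = np.sort(asc[:n_down])
    return up, down


def marker_table(expr: np.ndarray, labels: np.ndarray,
                 gene_names: list[str] | None = None,
                 n_up: int = 5, n_down: int = 5) -> pd.DataFrame:
    """One-vs-rest marker table over all classes.

    Returns a tidy frame (gene, class, snr, regulation) mirroring the usual
    up/down marker listing per class.
    """
    X = np.asarray(expr, dtype=float)
    labels = np.asarray(labels).ravel()
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(X.shape[0])]
    rows = []
    for cls in np.unique(labels):
        snr = snr_scores(X, labels == cls)
        up, down = select_markers(snr, n_up=n_up, n_down=n_down)
        for i in up:
            rows.append((gene_names[i], cls, snr[i], "up"))
        for i in down:
            rows.append((gene_names[i], cls, snr[i], "down"))
    return pd.DataFrame(rows, columns=["gene", "class", "snr", "regulation"])
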