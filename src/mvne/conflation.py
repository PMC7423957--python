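"""Combining per-view neighbour distributions into one unified distribution.

Conflation combines several probability distributions by their normalized
elementwise product.  It minimizes the maximal loss of Shannon information
and — unlike plain averaging — automatically weights each input by its
precision: a sharply peaked (accurate) view dominates a diffuse (noisy) one.

For the multi-view neighbour distributions, each pair (i, j) is combined
with a binary odds-style form: the product of "j is the neighbour"
probabilities against the product of "j is not the neighbour" masses,

    p_ij = prod_v p^v_ij / (prod_v p^v_ij + prod_v (sum_{k != j} p^v_ik)),

computed in log-space to avoid underflow.  Rows are then renormalized
(the raw form is not row-stochastic) and the matrix is symmetrized into a
joint distribution p_ij <- (p_ij + p_ji) / (2n), so the whole matrix sums
to one.

Incomplete views are handled case-wise: samples occurring in a single view
keep that view's row; pairs of multi-view samples are conflated over the
views containing both.  With complete data the case-wise rule reduces
exactly to the complete-data formula.

The AvgProb (mean of probabilities) and AvgData (mean of distance matrices)
baseline combiners live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

from .affinity import ViewProbability, probabilities_from_sq_distances

__all__ = [
    "UnifiedProbability",
    "conflate_discrete",
    "conflate_views_complete",
    "conflate_views_incomplete",
    "average_probabilities",
    "average_data",
]

#: entries are floored to this before any log (KL) use
PROB_FLOOR = 1e-12


@dataclass
class UnifiedProbability:
    """Symmetric joint neighbour distribution over all samples.

    When ``renormalized`` is True the matrix sums to one (the contract the
    embedding cost assumes); the literal un-renormalized combination is kept
    reachable for fidelity experiments.
    """

    P: np.ndarray
    mode: str
    renormalized: bool = True

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)

    def floored(self) -> np.ndarray:
        """Copy of P with off-diagonal entries floored for use inside KL."""
        P = np.maximum(self.P, PROB_FLOOR)
        np.fill_diagonal(P, 0.0)
        return P


def conflate_discrete(dists: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Conflation of discrete distributions: the normalized elementwise product."""
    arrs = [np.asarray(d, dtype=float) for d in dists]
    if not arrs:
        raise ValueError("need at least one distribution")
    size = arrs[0].size
    for d in arrs:
        if d.size != size:
            raise ValueError("distributions must share support size")
        if np.any(d < 0):
            raise ValueError("distributions must be non-negative")
    prod = np.ones(size)
    for d in arrs:
        prod = prod * d
    total = prod.sum()
    if total <= 0:
        raise ValueError("disjoint supports: product is identically zero")
    return prod / total


def _normalize_and_symmetrize(P: np.ndarray, renormalize: bool) -> np.ndarray:
    """Row-renormalize (optional) then symmetrize into a joint distribution."""
    P = P.copy()
    np.fill_diagonal(P, 0.0)
    n = P.shape[0]
    if renormalize:
        sums = P.sum(axis=1, keepdims=True)
        dead = sums[:, 0] <= 0
        if dead.any():
            warnings.warn(f"{int(dead.sum())} rows had zero mass; uniform fallback")
            P[dead] = 1.0
            np.fill_diagonal(P, 0.0)
            sums = P.sum(axis=1, keepdims=True)
        P = P / sums
    return (P + P.T) / (2.0 * n)


def _conflate_masked(view_probs: list[ViewProbability],
                     presence: np.ndarray) -> np.ndarray:
    """Case-wise conflation; with all-true presence this IS the complete rule.

    Returns the raw (pre-renormalization, pre-symmetrization) matrix.
    """
    m = len(view_probs)
    n = view_probs[0].probs.shape[0]
    presence = np.asarray(presence, dtype=bool)
    views_per_sample = presence.sum(axis=1)

    # log p and log(1 - p) per view, only where both samples are present
    log_num = np.zeros((n, n))
    log_den = np.zeros((n, n))
    for v, vp in enumerate(view_probs):
        pv = np.clip(vp.probs, 0.0, 1.0)
        pair = np.outer(presence[:, v], presence[:, v])
        np.fill_diagonal(pair, False)
        with np.errstate(divide="ignore"):
            lp = np.where(pair, np.log(np.maximum(pv, PROB_FLOOR)), 0.0)
            l1p = np.where(pair, np.log1p(-np.minimum(pv, 1.0 - PROB_FLOOR)), 0.0)
        log_num += lp
        log_den += l1p

    shared = np.zeros((n, n), dtype=int)
    for v in range(m):
        shared += np.outer(presence[:, v], presence[:, v]).astype(int)

    # case (c): both samples occur somewhere together — conflate over shared views
    P = np.where(shared > 0, expit(log_num - log_den), 0.0)

    single = views_per_sample == 1
    multi = views_per_sample > 1
    if single.any():
        # view index of each single-view sample
        only_view = presence.argmax(axis=1)
        # case (b): row i occurs in only one view -> that view's row as-is
        for i in np.where(single)[0]:
            P[i, :] = view_probs[only_view[i]].probs[i, :]
        # case (a): j single-view, i multi-view -> p^v_ij / m (0 if i not in v)
        for j in np.where(single)[0]:
            v = only_view[j]
            rows = multi.copy()
            P[rows, j] = np.where(
                presence[rows, v], view_probs[v].probs[rows, j] / m, 0.0)
    np.fill_diagonal(P, 0.0)
    return P


def conflate_views_complete(view_probs: list[ViewProbability],
                            renormalize: bool = True) -> UnifiedProbability:
    """Conflate fully-present views into one unified joint distribution."""
    n = view_probs[0].probs.shape[0]
    for vp in view_probs:
        if vp.present is not None and not vp.present.all():
            raise ValueError("complete conflation requires all samples present; "
                             "use conflate_views_incomplete")
    presence = np.ones((n, len(view_probs)), dtype=bool)
    P = _conflate_masked(view_probs, presence)
    return UnifiedProbability(P=_normalize_and_symmetrize(P, renormalize),
                              mode="conflation-complete", renormalized=renormalize)


def conflate_views_incomplete(view_probs: list[ViewProbability],
                              presence: np.ndarray,
                              renormalize: bool = True) -> UnifiedProbability:
    """Case-wise conflation for incomplete views.

    Reduces bitwise to :func:`conflate_views_complete` when every sample is
    present in every view.  Pairs sharing no view (and fitting neither
    single-view case) get probability zero.
    """
    presence = np.asarray(presence, dtype=bool)
    if not presence.any(axis=1).all():
        raise ValueError("every sample must occur in at least one view")
    P = _conflate_masked(view_probs, presence)
    mode = "conflation-complete" if presence.all() else "conflation-incomplete"
    return UnifiedProbability(P=_normalize_and_symmetrize(P, renormalize),
                              mode=mode, renormalized=renormalize)


def average_probabilities(view_probs: list[ViewProbability],
                          presence: np.ndarray | None = None) -> UnifiedProbability:
    """AvgProb baseline: arithmetic mean of the per-view rows, then symmetrize.

    Averaging weights every view equally regardless of its accuracy and can
    produce multi-modal rows — the behaviour conflation is designed to avoid.
    """
    n = view_probs[0].probs.shape[0]
    if presence is None:
        presence = np.ones((n, len(view_probs)), dtype=bool)
    presence = np.asarray(presence, dtype=bool)
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for v, vp in enumerate(view_probs):
        pair = np.outer(presence[:, v], presence[:, v])
        num += np.where(pair, vp.probs, 0.0)
        cnt += pair
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(cnt > 0, num / np.maximum(cnt, 1), 0.0)
    return UnifiedProbability(P=_normalize_and_symmetrize(P, True),
                              mode="avgprob", renormalized=True)


def average_data(views: list[np.ndarray], k: int,
                 presence: np.ndarray | None = None,
                 tol: float = 1e-5) -> UnifiedProbability:
    """AvgData baseline: mean of per-view Euclidean distance matrices.

    The averaged distances feed the same entropy-calibrated Gaussian rows
    used for a single view, followed by the usual symmetrization.  Pairs
    absent from every view are masked (infinite distance).
    """
    views = [np.asarray(V, dtype=float) for V in views]
    n = views[0].shape[0]
    if presence is None:
        presence = np.ones((n, len(views)), dtype=bool)
    presence = np.asarray(presence, dtype=bool)
    dsum = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for v, V in enumerate(views):
        D = squareform(pdist(V, metric="euclidean"))
        pair = np.outer(presence[:, v], presence[:, v])
        dsum += np.where(pair, D, 0.0)
        cnt += pair
    if np.any((cnt == 0) & ~np.eye(n, dtype=bool)):
        warnings.warn("some pairs share no view; treated as infinitely distant")
    with np.errstate(invalid="ignore", divide="ignore"):
        Davg = np.where(cnt > 0, dsum / np.maximum(cnt, 1), np.inf)
    np.fill_diagonal(Davg, 0.0)
    probs, _ = probabilities_from_sq_distances(Davg ** 2, k, tol=tol)
    return UnifiedProbability(P=_normalize_and_symmetrize(probs, True),
                              mode="avgdata", renormalized=True)
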