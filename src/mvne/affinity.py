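"""Per-view neighbour probability distributions.

For every sample *i* in a view, a Gaussian centred at *i* turns distances to
the other samples into a conditional distribution over potential neighbours:

    p_{j|i} = exp(-||x_i - x_j||^2 / (2 sigma_i^2)) / sum_{k != i} exp(...)

The per-sample bandwidth ``sigma_i`` is calibrated so that the Shannon
entropy (in nats) of row *i* equals ``log k``, where *k* is the effective
number of neighbours — the same perplexity-style calibration used by
stochastic neighbour embedding.  Each row sums to one over the samples
present in the view; the diagonal is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.special import logsumexp

__all__ = [
    "ViewProbability",
    "pairwise_scaled_distances",
    "calibrate_sigma",
    "view_probabilities",
    "probabilities_from_sq_distances",
    "row_entropy",
]

SIGMA_LO = 1e-10
SIGMA_HI = 1e10


@dataclass
class ViewProbability:
    """Row-conditional neighbour distribution of one view.

    ``probs[i, j]`` is the probability that sample *i* picks *j* as its
    neighbour; rows sum to 1 over present samples, the diagonal is zero.
    For incomplete views the rows/columns of absent samples are zero and
    ``present`` marks which rows are meaningful.
    """

    probs: np.ndarray
    sigmas: np.ndarray
    k_eff: int
    present: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.present is None:
            self.present = np.ones(self.probs.shape[0], dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)


def pairwise_scaled_distances(Xv: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Scaled squared Euclidean distances d_ij^2 = ||x_i - x_j||^2 / (2 sigma_i^2).

    Row-specific bandwidths make the result asymmetric in general.
    """
    Xv = np.asarray(Xv, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be strictly positive")
    D2 = squareform(pdist(Xv, metric="sqeuclidean"))
    return D2 / (2.0 * sigmas[:, None] ** 2)


def _row_distribution(d2_row: np.ndarray, beta: float) -> np.ndarray:
    """Gaussian row distribution at precision ``beta`` = 1/(2 sigma^2), stable."""
    logits = -beta * d2_row
    return np.exp(logits - logsumexp(logits))


def _row_entropy_at(d2_row: np.ndarray, beta: float) -> float:
    logits = -beta * d2_row
    lz = logsumexp(logits)
    p = np.exp(logits - lz)
    # H = log Z + beta * <d2>
    return float(lz + beta * np.dot(p, d2_row))


def row_entropy(p_row: np.ndarray) -> float:
    """Shannon entropy in nats of one probability row (zeros contribute 0)."""
    p = np.asarray(p_row, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def calibrate_sigma(distances_row: np.ndarray, k: int, tol: float = 1e-5,
                    max_bisect: int = 50) -> float:
    """Find sigma_i with row entropy within ``tol`` of log k.

    ``distances_row`` holds the unscaled squared Euclidean distances from
    sample *i* to its potential neighbours (self excluded).  Entropy is
    monotone non-decreasing in sigma, so a doubling bracket followed by
    bisection converges; if the target is unreachable (e.g. fewer distinct
    neighbours than exp(log k)) the boundary sigma is returned with a
    warning.
    """
    d2 = np.asarray(distances_row, dtype=float)
    if d2.size < 2:
        raise ValueError("need at least 2 neighbours to calibrate")
    if k < 2:
        raise ValueError("k must be >= 2")
    target = np.log(k)

    def entropy_of_sigma(sigma: float) -> float:
        return _row_entropy_at(d2, 1.0 / (2.0 * sigma * sigma))

    sigma = 1.0
    h = entropy_of_sigma(sigma)
    if abs(h - target) <= tol:
        return sigma
    lo, hi = None, None
    if h < target:
        lo = sigma
        while h < target and sigma < SIGMA_HI:
            sigma *= 2.0
            h = entropy_of_sigma(sigma)
            if h < target:
                lo = sigma
        hi = sigma
    else:
        hi = sigma
        while h > target and sigma > SIGMA_LO:
            sigma /= 2.0
            h = entropy_of_sigma(sigma)
            if h > target:
                hi = sigma
        lo = sigma
    if not (SIGMA_LO < sigma < SIGMA_HI):
        warnings.warn(
            f"entropy target log({k}) unreachable; returning boundary sigma={sigma:g}"
        )
        return float(np.clip(sigma, SIGMA_LO, SIGMA_HI))
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        h = entropy_of_sigma(mid)
        if abs(h - target) <= tol:
            return mid
        if h < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def probabilities_from_sq_distances(D2: np.ndarray, k: int,
                                    tol: float = 1e-5) -> tuple[np.ndarray, np.ndarray]:
    """Entropy-calibrated Gaussian rows from a squared-distance matrix.

    Returns ``(probs, sigmas)``; ``probs`` has zero diagonal and rows summing
    to 1.  Rows whose distances are all zero (exact duplicates of every other
    point) fall back to a uniform row.
    """
    D2 = np.asarray(D2, dtype=float)
    n = D2.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of samples {n}")
    probs = np.zeros((n, n))
    sigmas = np.ones(n)
    idx = np.arange(n)
    for i in range(n):
        others = idx != i
        d2 = D2[i, others]
        if np.all(d2 == d2[0]):
            # equidistant (incl. all-duplicate) row: any sigma gives uniform
            if d2[0] == 0.0 and n > 2:
                warnings.warn(f"row {i}: all neighbours coincide; uniform fallback")
            probs[i, others] = 1.0 / (n - 1)
            continue
        sigmas[i] = calibrate_sigma(d2, k, tol=tol)
        probs[i, others] = _row_distribution(d2, 1.0 / (2.0 * sigmas[i] ** 2))
    return probs, sigmas


def view_probabilities(Xv: np.ndarray, k: int, tol: float = 1e-5,
                       present: np.ndarray | None = None) -> ViewProbability:
    """Neighbour distribution of one view.

    When ``present`` is given, probabilities are computed among present
    samples only and embedded into the full n x n matrix with zero
    rows/columns for absent samples.
    """
    Xv = np.asarray(Xv, dtype=float)
    n = Xv.shape[0]
    if present is None:
        probs, sigmas = probabilities_from_sq_distances(
            squareform(pdist(Xv, metric="sqeuclidean")), k, tol=tol)
        return ViewProbability(probs=probs, sigmas=sigmas, k_eff=k)
    present = np.asarray(present, dtype=bool)
    sub = Xv[present]
    sub_probs, sub_sigmas = probabilities_from_sq_distances(
        squareform(pdist(sub, metric="sqeuclidean")), k, tol=tol)
    probs = np.zeros((n, n))
    rows = np.where(present)[0]
    probs[np.ix_(rows, rows)] = sub_probs
    sigmas = np.ones(n)
    sigmas[rows] = sub_sigmas
    return ViewProbability(probs=probs, sigmas=sigmas, k_eff=k, present=present)
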