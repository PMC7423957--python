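"""Low-dimensional embedding by KL minimization.

Given the unified high-dimensional joint distribution P, low-dimensional
coordinates Y induce a Student-t (one degree of freedom) joint distribution

    q_ij = (1 + ||y_i - y_j||^2)^-1 / sum_{l != k} (1 + ||y_l - y_k||^2)^-1,

and Y is moved to minimize C = KL(P || Q) with the closed-form gradient

    dC/dy_i = 4 sum_j (p_ij - q_ij) (1 + ||y_i - y_j||^2)^-1 (y_i - y_j).

Optimization is full-batch gradient descent with a momentum schedule
(initial 0.5, final 0.9) and Jacobs' delta-bar-delta per-coordinate gains.
Y is recentred to zero mean each iteration for numerical stability; the
cost is translation invariant so this does not change the objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .conflation import PROB_FLOOR, UnifiedProbability

__all__ = [
    "LowDimProbability",
    "EmbeddingState",
    "OptimizerSettings",
    "compute_q",
    "kl_cost",
    "kl_gradient",
    "optimize",
]


@dataclass
class LowDimProbability:
    """Student-t joint distribution in the embedding space."""

    Q: np.ndarray
    S: float  # normalizer sum_{k != l} (1 + d^2)^-1


@dataclass
class OptimizerSettings:
    """Gradient-descent settings.

    ``eta`` is the base learning rate, multiplied per-coordinate by adaptive
    gains: a gain grows by ``gain_up`` when the gradient sign disagrees with
    the running update (still making progress) and shrinks by ``gain_down``
    otherwise, never below ``min_gain``.  Momentum switches from
    ``momentum_init`` to ``momentum_final`` at ``momentum_switch``.
    """

    n_iter: int = 2000
    eta: float = 200.0
    momentum_init: float = 0.5
    momentum_final: float = 0.9
    momentum_switch: int = 250
    min_gain: float = 0.01
    gain_up: float = 0.2
    gain_down: float = 0.8
    recenter: bool = True
    early_exaggeration: float = 1.0   # off by default
    exaggeration_iters: int = 0
    init_rescale: float | None = None
    grad_tol: float = 1e-12   # stop moving once the gradient sup-norm vanishes
    seed: int = 0


@dataclass
class EmbeddingState:
    Y: np.ndarray
    velocity: np.ndarray
    gains: np.ndarray
    iteration: int
    eta: float
    momentum: float
    cost_trace: list[float] = field(default_factory=list)


def _kernel(Y: np.ndarray) -> np.ndarray:
    """(1 + ||y_i - y_j||^2)^-1 with zero diagonal."""
    D2 = squareform(pdist(np.asarray(Y, dtype=float), metric="sqeuclidean"))
    W = 1.0 / (1.0 + D2)
    np.fill_diagonal(W, 0.0)
    return W


def compute_q(Y: np.ndarray) -> LowDimProbability:
    """Student-t neighbour distribution of the embedding."""
    W = _kernel(Y)
    S = W.sum()
    if S <= 0:
        raise ValueError("need at least 2 samples")
    return LowDimProbability(Q=W / S, S=float(S))


def _as_P(P) -> np.ndarray:
    if isinstance(P, UnifiedProbability):
        return P.P
    return np.asarray(P, dtype=float)


def kl_cost(P, Q) -> float:
    """C = sum_ij p_ij log(p_ij / q_ij); zero-p terms contribute nothing."""
    Pm = _as_P(P)
    Qm = Q.Q if isinstance(Q, LowDimProbability) else np.asarray(Q, dtype=float)
    Qf = np.maximum(Qm, PROB_FLOOR)
    mask = Pm > 0
    return float((Pm[mask] * np.log(Pm[mask] / Qf[mask])).sum())


def kl_gradient(P, Y: np.ndarray) -> np.ndarray:
    """Closed-form gradient of the KL cost with respect to Y."""
    Pm = _as_P(P)
    Y = np.asarray(Y, dtype=float)
    W = _kernel(Y)
    Q = W / W.sum()
    M = (Pm - Q) * W
    # 4 * sum_j M_ij (y_i - y_j) = 4 * (rowsum(M) * y_i - M @ Y)
    return 4.0 * (M.sum(axis=1)[:, None] * Y - M @ Y)


def optimize(P, Y_init: np.ndarray,
             settings: OptimizerSettings | None = None) -> EmbeddingState:
    """Full-batch gradient descent on KL(P || Q) from ``Y_init``.

    Returns the final :class:`EmbeddingState` including the per-iteration
    cost trace.  On a non-finite cost the last finite state is returned with
    a warning.
    """
    if settings is None:
        settings = OptimizerSettings()
    Pm = _as_P(P).copy()
    Y = np.array(Y_init, dtype=float, copy=True)
    if settings.init_rescale is not None:
        # shrink the start configuration to a small spread; gradient descent
        # then grows the map instead of having to untangle a large one
        spread = Y.std()
        if spread > 0:
            Y *= settings.init_rescale / spread
    n, d = Y.shape
    if Pm.shape != (n, n):
        raise ValueError(f"P shape {Pm.shape} does not match Y rows {n}")
    velocity = np.zeros_like(Y)
    gains = np.ones_like(Y)
    trace: list[float] = []
    st = settings
    momentum = st.momentum_init
    for it in range(st.n_iter):
        exag = st.early_exaggeration if it < st.exaggeration_iters else 1.0
        grad = kl_gradient(Pm * exag if exag != 1.0 else Pm, Y)
        if np.abs(grad).max() < st.grad_tol:
            # stationary point: a zero gradient must not be amplified by
            # the momentum/gain dynamics
            trace.append(kl_cost(Pm, compute_q(Y)))
            continue
        momentum = st.momentum_init if it < st.momentum_switch else st.momentum_final
        # delta-bar-delta: grow gain while signs of grad and update disagree
        same_sign = np.sign(grad) == np.sign(velocity)
        gains = np.where(same_sign, gains * st.gain_down, gains + st.gain_up)
        np.maximum(gains, st.min_gain, out=gains)
        velocity = momentum * velocity - st.eta * gains * grad
        Y = Y + velocity
        if st.recenter:
            Y -= Y.mean(axis=0)
        cost = kl_cost(Pm, compute_q(Y))
        if not np.isfinite(cost):
            warnings.warn(f"non-finite cost at iteration {it}; aborting early")
            break
        trace.append(cost)
    return EmbeddingState(Y=Y, velocity=velocity, gains=gains,
                          iteration=len(trace), eta=st.eta, momentum=momentum,
                          cost_trace=trace)
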