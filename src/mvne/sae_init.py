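"""Initial embedding via a stacked denoising autoencoder (SDAE).

The concatenated multi-view matrix is compressed through a symmetric
bottleneck network  d -> h -> d_emb -> h -> d  (default h = 500).  Each
encoder/decoder pair is first pretrained greedily as a denoising autoencoder
— dropout corruption on its input and hidden activations, mean squared
reconstruction error — then the stack is fine-tuned end to end and the
decoder is discarded.  The bottleneck activations of a clean (uncorrupted)
forward pass are the initial embedding ``Y_init``.

The network is small (patient-cohort sized inputs) and is implemented
directly on numpy with an Adam optimizer; everything is seeded and
deterministic.  A PCA initializer is available as a cheap alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "SAEConfig",
    "InitialEmbedding",
    "StackedDenoisingAutoencoder",
    "pretrain_layer",
    "build_and_finetune",
    "pca_embedding",
]


@dataclass
class SAEConfig:
    """Hyper-parameters of the stacked denoising autoencoder.

    ``hidden_size`` and ``d_emb`` define the symmetric layer sizes
    [d, hidden, d_emb, hidden, d]; dropout is the corruption rate applied to
    layer inputs during training only.
    """

    d_emb: int = 80
    hidden_size: int = 500
    dropout_rate: float = 0.05
    pretrain_epochs: int = 200
    finetune_epochs: int = 400
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.d_emb < 1 or self.hidden_size < 1:
            raise ValueError("layer sizes must be positive")


@dataclass
class InitialEmbedding:
    Y_init: np.ndarray
    reconstruction_loss_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------- numpy net

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Adam:
    """Per-parameter Adam state."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _dropout(rng: np.random.Generator, X: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0.0:
        return X
    mask = rng.random(X.shape) >= rate
    return X * mask / (1.0 - rate)


def _epoch_batches(rng: np.random.Generator, n: int, batch_size: int):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def pretrain_layer(input: np.ndarray, hidden_size: int, cfg: SAEConfig,
                   rng: np.random.Generator | None = None,
                   decoder_activation: str = "linear",
                   ) -> tuple[dict[str, np.ndarray], np.ndarray, list[float]]:
    """Train one denoising autoencoder layer.

    The corrupted input (dropout) is encoded with ReLU, the hidden
    activations are corrupted again, and the decoder reconstructs the clean
    input under mean squared error.  Returns the trained weights, the clean
    encoding of the input, and the per-epoch loss trace.
    """
    X = np.asarray(input, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("pretrain input contains non-finite values")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, d = X.shape
    W1 = _glorot(rng, d, hidden_size)
    b1 = np.zeros(hidden_size)
    W2 = _glorot(rng, hidden_size, d)
    b2 = np.zeros(d)
    opt = _Adam([W1, b1, W2, b2], cfg.learning_rate)
    batch = min(n, cfg.batch_size)
    use_relu_out = decoder_activation == "relu"
    trace: list[float] = []
    for _ in range(cfg.pretrain_epochs):
        losses = []
        for idx in _epoch_batches(rng, n, batch):
            xb = X[idx]
            xc = _dropout(rng, xb, cfg.dropout_rate)
            z1 = xc @ W1 + b1
            h1 = _relu(z1)
            hc = _dropout(rng, h1, cfg.dropout_rate)
            z2 = hc @ W2 + b2
            y = _relu(z2) if use_relu_out else z2
            err = y - xb
            loss = float((err ** 2).mean())
            if not np.isfinite(loss):
                raise RuntimeError("NaN/inf loss during layer pretraining")
            losses.append(loss)
            # backprop of mean squared error
            g_y = 2.0 * err / err.size
            g_z2 = g_y * (z2 > 0) if use_relu_out else g_y
            gW2 = hc.T @ g_z2
            gb2 = g_z2.sum(axis=0)
            g_h = g_z2 @ W2.T
            g_z1 = g_h * (z1 > 0)
            gW1 = xc.T @ g_z1
            gb1 = g_z1.sum(axis=0)
            opt.step([gW1, gb1, gW2, gb2])
        trace.append(float(np.mean(losses)))
    encoded = _relu(X @ W1 + b1)  # clean pass, no corruption
    weights = {"W1": W1, "b1": b1, "W2": W2, "b2": b2}
    return weights, encoded, trace


class StackedDenoisingAutoencoder(TransformerMixin, BaseEstimator):
    """Sklearn-style SDAE transformer producing the bottleneck embedding.

    Parameters mirror :class:`SAEConfig`; ``fit`` runs greedy layer-wise
    pretraining followed by end-to-end fine-tuning, ``transform`` returns the
    clean bottleneck encoding.

    Attributes
    ----------
    weights_ : list of dict
        Encoder/decoder parameters of the fine-tuned stack.
    loss_trace_ : list of float
        Per-epoch fine-tuning reconstruction MSE.
    pretrain_traces_ : list of list of float
        Per-layer pretraining loss traces.
    """

    def __init__(self, d_emb: int = 80, hidden_size: int = 500,
                 dropout_rate: float = 0.05, pretrain_epochs: int = 200,
                 finetune_epochs: int = 400, batch_size: int = 64,
                 learning_rate: float = 1e-3, random_state: int = 0):
        self.d_emb = d_emb
        self.hidden_size = hidden_size
        self.dropout_rate = dropout_rate
        self.pretrain_epochs = pretrain_epochs
        self.finetune_epochs = finetune_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _config(self) -> SAEConfig:
        return SAEConfig(
            d_emb=self.d_emb, hidden_size=self.hidden_size,
            dropout_rate=self.dropout_rate,
            pretrain_epochs=self.pretrain_epochs,
            finetune_epochs=self.finetune_epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            seed=self.random_state)

    def fit(self, X: np.ndarray, y=None) -> "StackedDenoisingAutoencoder":
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if cfg.d_emb >= d:
            warnings.warn(f"d_emb={cfg.d_emb} >= input dim {d}: no compression")
        rng = np.random.default_rng(cfg.seed)

        # greedy pretraining: d -> hidden (linear decode of z-scored reals),
        # hidden -> d_emb (ReLU decode of non-negative activations)
        l1, h1, t1 = pretrain_layer(X, cfg.hidden_size, cfg, rng=rng,
                                    decoder_activation="linear")
        l2, _, t2 = pretrain_layer(h1, cfg.d_emb, cfg, rng=rng,
                                   decoder_activation="relu")
        self.pretrain_traces_ = [t1, t2]

        # stack: enc1, enc2, dec2, dec1; fine-tune end to end on MSE
        W = [l1["W1"].copy(), l2["W1"].copy(), l2["W2"].copy(), l1["W2"].copy()]
        b = [l1["b1"].copy(), l2["b1"].copy(), l2["b2"].copy(), l1["b2"].copy()]
        params: list[np.ndarray] = [*W, *b]
        opt = _Adam(params, cfg.learning_rate)
        batch = min(n, cfg.batch_size)
        trace: list[float] = []
        for _ in range(cfg.finetune_epochs):
            losses = []
            for idx in _epoch_batches(rng, n, batch):
                xb = X[idx]
                a = _dropout(rng, xb, cfg.dropout_rate)
                zs, acts = [], [a]
                for li in range(4):
                    z = acts[-1] @ params[li] + params[4 + li]
                    zs.append(z)
                    acts.append(z if li == 3 else _relu(z))  # linear output
                err = acts[-1] - xb
                loss = float((err ** 2).mean())
                if not np.isfinite(loss):
                    raise RuntimeError("NaN/inf loss during fine-tuning")
                losses.append(loss)
                g = 2.0 * err / err.size
                grads_W = [np.empty(0)] * 4
                grads_b = [np.empty(0)] * 4
                for li in range(3, -1, -1):
                    g_z = g if li == 3 else g * (zs[li] > 0)
                    grads_W[li] = acts[li].T @ g_z
                    grads_b[li] = g_z.sum(axis=0)
                    g = g_z @ params[li].T
                opt.step([*grads_W, *grads_b])
            trace.append(float(np.mean(losses)))
        self.loss_trace_ = trace
        self.weights_ = [
            {"W": params[0], "b": params[4]},
            {"W": params[1], "b": params[5]},
            {"W": params[2], "b": params[6]},
            {"W": params[3], "b": params[7]},
        ]
        self.n_features_in_ = d
        self.embedding_ = self.transform(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Clean (uncorrupted) forward pass through the encoder half."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("not fitted")
        a = np.asarray(X, dtype=float)
        for layer in self.weights_[:2]:
            a = _relu(a @ layer["W"] + layer["b"])
        return a

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for li, layer in enumerate(self.weights_):
            z = a @ layer["W"] + layer["b"]
            a = z if li == 3 else _relu(z)
        return a


def build_and_finetune(X, cfg: SAEConfig) -> InitialEmbedding:
    """Functional wrapper: concatenated matrix -> initial embedding."""
    data = X.data if hasattr(X, "data") and not isinstance(X, np.ndarray) else X
    est = StackedDenoisingAutoencoder(
        d_emb=cfg.d_emb, hidden_size=cfg.hidden_size,
        dropout_rate=cfg.dropout_rate, pretrain_epochs=cfg.pretrain_epochs,
        finetune_epochs=cfg.finetune_epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, random_state=cfg.seed)
    est.fit(np.asarray(data, dtype=float))
    return InitialEmbedding(Y_init=est.embedding_,
                            reconstruction_loss_trace=est.loss_trace_)


def pca_embedding(X, d_emb: int, seed: int = 0) -> InitialEmbedding:
    """PCA alternative to the autoencoder initializer."""
    data = np.asarray(X.data if hasattr(X, "data") and not isinstance(X, np.ndarray)
                      else X, dtype=float)
    n, d = data.shape
    k = min(d_emb, min(n, d))
    Y = PCA(n_components=k, random_state=seed).fit_transform(data)
    if k < d_emb:
        Y = np.hstack([Y, np.zeros((n, d_emb - k))])
    return InitialEmbedding(Y_init=Y, reconstruction_loss_trace=[])
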