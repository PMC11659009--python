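"""A small fully-connected regression network in plain numpy.

Architecture and training schedule follow the deep-network configuration
used for biomass estimation here: four hidden ReLU layers (256, 128, 64,
32 units), dropout 0.2 after the first hidden layer, Adam with initial
learning rate 1e-3 decayed by a factor 0.9 every 100 epochs, mean-squared
error loss, 600 epochs, batch size min(256, n).  Being pure numpy it is
bit-deterministic for a fixed seed regardless of thread count.

Inputs and targets are expected pre-standardized by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPRegressor"]


class MLPRegressor:
    def __init__(self, hidden=(256, 128, 64, 32), dropout: float = 0.2,
                 epochs: int = 600, batch_size: int = 256, lr: float = 1e-3,
                 lr_decay: float = 0.9, lr_decay_every: int = 100,
                 seed: int = 0):
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_decay_every = lr_decay_every
        self.seed = seed
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None

    # -- internals ----------------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features, *self.hidden, 1]
        self.weights_, self.biases_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization for ReLU layers
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights_.append(w)
            self.biases_.append(np.zeros(fan_out))

    def _forward(self, X, rng=None):
        """Returns activations and dropout masks (training mode iff rng)."""
        acts = [X]
        masks = []
        a = X
        n_hidden = len(self.hidden)
        for i, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            z = a @ w + b
            if i < n_hidden:
                a = np.maximum(z, 0.0)
                if i == 0 and rng is not None and self.dropout > 0:
                    keep = 1.0 - self.dropout
                    mask = (rng.random(a.shape) < keep) / keep
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = z
            acts.append(a)
        return acts, masks

    # -- API ----------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        self._init_params(d, rng)
        ms = [np.zeros_like(w) for w in self.weights_]
        vs = [np.zeros_like(w) for w in self.weights_]
        mbs = [np.zeros_like(b) for b in self.biases_]
        vbs = [np.zeros_like(b) for b in self.biases_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        batch = min(self.batch_size, n)
        step = 0
        for epoch in range(self.epochs):
            lr = self.lr * self.lr_decay ** (epoch // self.lr_decay_every)
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                acts, masks = self._forward(X[idx], rng=rng)
                pred = acts[-1]
                m_b = len(idx)
                delta = 2.0 * (pred - y[idx]) / m_b  # dMSE/dpred
                step += 1
                grads_w = [None] * len(self.weights_)
                grads_b = [None] * len(self.biases_)
                for i in range(len(self.weights_) - 1, -1, -1):
                    grads_w[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.weights_[i].T
                        delta = delta * (acts[i] > 0)
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                for i in range(len(self.weights_)):
                    for g, m_, v_, p in ((grads_w[i], ms, vs, self.weights_),
                                         (grads_b[i], mbs, vbs, self.biases_)):
                        m_[i] = beta1 * m_[i] + (1 - beta1) * g
                        v_[i] = beta2 * v_[i] + (1 - beta2) * g * g
                        mhat = m_[i] / (1 - beta1 ** step)
                        vhat = v_[i] / (1 - beta2 ** step)
                        p[i] = p[i] - lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        acts, _ = self._forward(np.asarray(X, dtype=float), rng=None)
        return acts[-1].ravel()
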