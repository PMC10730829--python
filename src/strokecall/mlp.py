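"""A small feed-forward network for sparse bag-of-words inputs.

Implemented directly in numpy so that the exact pre-sigmoid logit is
available everywhere (threshold centring and the occlusion analysis both
operate in logit space), and so that initialisation, minibatch order and
dropout are all driven by one seed.  ReLU hidden layers, inverted dropout,
L2 weight decay, Adam updates, binary cross-entropy on the final scalar
logit with a sigmoid output nonlinearity.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["DenseNet", "sigmoid", "logit"]

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


def sigmoid(z):
    """Numerically stable logistic function."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=np.float64)))


def logit(p):
    p = np.asarray(p, dtype=np.float64)
    return np.log(p) - np.log1p(-p)


class DenseNet:
    """MLP with ReLU hidden layers and a single scalar output logit."""

    def __init__(
        self,
        n_features: int,
        hidden_sizes: tuple[int, ...],
        dropout: float = 0.0,
        l2: float = 0.0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        sizes = [n_features, *hidden_sizes, 1]
        # He-normal fan-in initialisation suits the ReLU stack.
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(s) for s in sizes[1:]]
        self.dropout = float(dropout)
        self.l2 = float(l2)
        self._rng = rng
        self._step = 0
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]

    # -- inference ---------------------------------------------------------
    def logits(self, X) -> np.ndarray:
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return np.asarray(a @ self.W[-1] + self.b[-1]).ravel()

    def scores(self, X) -> np.ndarray:
        return sigmoid(self.logits(X))

    # -- training ----------------------------------------------------------
    def train_step(self, X, y: np.ndarray, lr: float, pos_weight: float | None = None) -> float:
        """One Adam minibatch step on binary cross-entropy; returns the loss."""
        n = X.shape[0]
        y = np.asarray(y, dtype=np.float64)
        acts = [X]
        masks = []
        a = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(a @ W + b, 0.0)
            if self.dropout > 0.0:
                keep = 1.0 - self.dropout
                mask = (self._rng.random(h.shape) < keep) / keep
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
            a = h
        z = np.asarray(a @ self.W[-1] + self.b[-1]).ravel()
        p = sigmoid(z)

        w = np.ones_like(y) if pos_weight is None else np.where(y > 0.5, pos_weight, 1.0)
        eps = 1e-12
        loss = -np.mean(w * (y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps)))

        delta = ((p - y) * w / n)[:, None]
        gW, gb = [], []
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = acts[i]
            grad_w = a_prev.T @ delta
            if sparse.issparse(grad_w):
                grad_w = np.asarray(grad_w.todense())
            grad_w = np.asarray(grad_w) + self.l2 * self.W[i]
            gW.append(grad_w)
            gb.append(delta.sum(axis=0))
            if i > 0:
                delta = delta @ self.W[i].T
                delta[acts[i] <= 0.0] = 0.0
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
        gW.reverse()
        gb.reverse()

        self._step += 1
        t = self._step
        for i in range(len(self.W)):
            for param, grad, m, v in (
                (self.W[i], gW[i], self._mW, self._vW),
                (self.b[i], gb[i], self._mb, self._vb),
            ):
                m[i] = _ADAM_B1 * m[i] + (1 - _ADAM_B1) * grad
                v[i] = _ADAM_B2 * v[i] + (1 - _ADAM_B2) * grad**2
                m_hat = m[i] / (1 - _ADAM_B1**t)
                v_hat = v[i] / (1 - _ADAM_B2**t)
                param -= lr * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)
        return float(loss)

    # -- checkpointing -------------------------------------------------------
    def get_params(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_params(self, params: tuple[list[np.ndarray], list[np.ndarray]]) -> None:
        self.W = [w.copy() for w in params[0]]
        self.b = [b.copy() for b in params[1]]
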