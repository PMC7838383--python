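"""Minimal feed-forward neural network in numpy.

Purpose-built binary classifier: three ReLU hidden layers whose widths
halve successively, trained with Adam, inverted dropout on the input and
hidden layers, optional L1/L2 weight penalties or Gaussian input noise,
and early stopping on a validation carve-out.  Three objectives are
supported: categorical cross-entropy and binary cross-entropy on a 2-unit
head, and hinge loss on a single linear margin unit with +/-1 label coding.
Fully deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPBinaryClassifier"]

_LOSSES = ("categorical_ce", "binary_ce", "hinge")


def _relu(z):
    return np.maximum(z, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class MLPBinaryClassifier:
    """Three-hidden-layer ReLU network for like/dislike classification.

    Hidden widths are floor(d/2), floor(d/4), floor(d/8) for input width d.
    """

    def __init__(self, loss: str = "binary_ce", learning_rate: float = 0.001,
                 dropout: float = 0.5, epochs: int = 80, batch_size: int = 32,
                 patience: int = 10, start_epoch: int = 30,
                 val_fraction: float = 0.1,
                 regularization: str = "none", reg_strength: float = 1e-4,
                 noise_sd: float = 0.1, seed: int = 0):
        if loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}, got {loss!r}")
        if regularization not in ("none", "l1", "l2", "gaussian_noise"):
            raise ValueError(f"unknown regularization {regularization!r}")
        self.loss = loss
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        # cross-entropy training sits on a ~ln 2 plateau for the first few
        # dozen epochs under heavy dropout; early stopping engages only
        # after this warmup so the plateau is not mistaken for convergence
        self.start_epoch = start_epoch
        self.val_fraction = val_fraction
        self.regularization = regularization
        self.reg_strength = reg_strength
        self.noise_sd = noise_sd
        self.seed = seed

    # -- architecture -------------------------------------------------
    @staticmethod
    def hidden_sizes(input_dim: int) -> tuple[int, int, int]:
        if input_dim < 8:
            raise ValueError(f"input width {input_dim} too small (need >= 8)")
        return (input_dim // 2, input_dim // 4, input_dim // 8)

    def _init_params(self, input_dim: int, rng: np.random.Generator):
        out_dim = 1 if self.loss == "hinge" else 2
        sizes = (input_dim, *self.hidden_sizes(input_dim), out_dim)
        self.W_ = [rng.normal(0, np.sqrt(2.0 / sizes[i]),
                              size=(sizes[i], sizes[i + 1]))
                   for i in range(len(sizes) - 1)]
        self.b_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    # -- forward/backward ---------------------------------------------
    def _forward(self, X, rng=None):
        """Returns raw output scores and the per-layer caches."""
        drop = self.dropout if rng is not None else 0.0
        a = X
        if rng is not None and self.regularization == "gaussian_noise":
            a = a + rng.normal(0, self.noise_sd, size=a.shape)
        caches = []
        masks = []
        if drop > 0:
            m = (rng.random(a.shape) >= drop) / (1 - drop)
            a = a * m
            masks.append(m)
        else:
            masks.append(None)
        for i, (W, b) in enumerate(zip(self.W_, self.b_)):
            z = a @ W + b
            last = i == len(self.W_) - 1
            caches.append((a, z))
            if last:
                a = z
            else:
                a = _relu(z)
                if drop > 0:
                    m = (rng.random(a.shape) >= drop) / (1 - drop)
                    a = a * m
                    masks.append(m)
                else:
                    masks.append(None)
        return a, caches, masks

    def _output_grad(self, scores, y):
        """Mean loss and d(loss)/d(scores); y is 0/1 integer labels."""
        n = len(y)
        if self.loss == "categorical_ce":
            p = _softmax(scores)
            onehot = np.eye(2)[y]
            loss = -np.mean(np.sum(onehot * np.log(p + 1e-12), axis=1))
            grad = (p - onehot) / n
        elif self.loss == "binary_ce":
            p = _sigmoid(scores)
            onehot = np.eye(2)[y]
            loss = -np.mean(onehot * np.log(p + 1e-12)
                            + (1 - onehot) * np.log(1 - p + 1e-12))
            grad = (p - onehot) / (n * 2)
        else:  # hinge on +/-1 coding, single margin unit
            s = np.where(y == 1, 1.0, -1.0)[:, None]
            margins = 1.0 - s * scores
            loss = float(np.mean(np.maximum(margins, 0.0)))
            grad = np.where(margins > 0, -s, 0.0) / n
        return loss, grad

    def _batch_loss(self, X, y):
        scores, _, _ = self._forward(X)
        loss, _ = self._output_grad(scores, y)
        return loss

    # -- training ------------------------------------------------------
    def fit(self, X, y):
        """Train on features X (n x d) and labels y in {0, 1}."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)

        n = len(X)
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        m = [np.zeros_like(w) for w in self.W_ + self.b_]
        v = [np.zeros_like(w) for w in self.W_ + self.b_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = None
        stall = 0
        for epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                scores, caches, masks = self._forward(xb, rng=rng)
                _, grad = self._output_grad(scores, yb)
                grads_W = [None] * len(self.W_)
                grads_b = [None] * len(self.b_)
                delta = grad
                for i in range(len(self.W_) - 1, -1, -1):
                    a_in, z = caches[i]
                    grads_W[i] = a_in.T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.W_[i].T
                        if masks[i] is not None:
                            delta = delta * masks[i]
                        delta = delta * (caches[i - 1][1] > 0)
                if self.regularization == "l2":
                    for i in range(len(self.W_)):
                        grads_W[i] = grads_W[i] + self.reg_strength * self.W_[i]
                elif self.regularization == "l1":
                    for i in range(len(self.W_)):
                        grads_W[i] = grads_W[i] + self.reg_strength * np.sign(self.W_[i])
                step += 1
                params = self.W_ + self.b_
                grads = grads_W + grads_b
                lr_t = self.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    p -= lr_t * m[j] / (np.sqrt(v[j]) + eps)
            if n_val:
                val_loss = self._batch_loss(Xval, yval)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = ([w.copy() for w in self.W_],
                                   [b.copy() for b in self.b_])
                    stall = 0
                else:
                    stall += 1
                    if epoch >= self.start_epoch and stall >= self.patience:
                        break
        if best_params is not None:
            self.W_, self.b_ = best_params
        return self

    # -- inference ------------------------------------------------------
    def decision_scores(self, X):
        scores, _, _ = self._forward(np.asarray(X, dtype=float))
        return scores

    def predict(self, X):
        scores = self.decision_scores(X)
        if self.loss == "hinge":
            return (scores[:, 0] > 0).astype(int)
        return scores.argmax(axis=1)
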