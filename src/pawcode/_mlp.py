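"""Minimal feed-forward classifier (numpy).

Dense ReLU network trained with Adam on class-weighted softmax
cross-entropy, with inverted dropout, L2 weight decay and early stopping on
validation balanced accuracy. Deterministic given the seed (initialization,
batch order and dropout masks all come from one generator).
"""

from __future__ import annotations

import numpy as np


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    """Unweighted mean of per-class recalls."""
    recalls = []
    for c in range(n_classes):
        mask = y_true == c
        if mask.any():
            recalls.append(float(np.mean(y_pred[mask] == c)))
    return float(np.mean(recalls))


class FeedForwardClassifier:
    """Fully connected softmax classifier with dropout and weighted loss."""

    def __init__(
        self,
        hidden: tuple[int, ...] = (200, 200, 200),
        dropout: float = 0.25,
        l2: float = 1e-4,
        lr: float = 1e-4,
        batch_size: int = 64,
        max_epochs: int = 120,
        patience: int = 10,
        seed: int | None = 0,
    ) -> None:
        self.hidden = hidden
        self.dropout = dropout
        self.l2 = l2
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _init(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        dims = [n_in, *self.hidden, n_out]
        self.W = [
            rng.standard_normal((a, b)).astype(np.float32) * np.sqrt(2.0 / a)
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.b = [np.zeros(b, dtype=np.float32) for b in dims[1:]]
        self._mW = [np.zeros_like(w) for w in self.W]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._mb = [np.zeros_like(b) for b in self.b]
        self._vb = [np.zeros_like(b) for b in self.b]
        self._t = 0

    def _forward(self, X, rng=None):
        acts = [X]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ W + b
            if i < len(self.W) - 1:
                z = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0:
                    mask = (rng.random(z.shape) >= self.dropout).astype(
                        np.float32
                    ) / (1.0 - self.dropout)
                    z = z * mask
            acts.append(z)
        logits = acts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        return acts, p

    def _adam(self, grads_W, grads_b):
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1.0 - b1**self._t
        corr2 = 1.0 - b2**self._t
        for i in range(len(self.W)):
            for param, grad, m, v in (
                (self.W[i], grads_W[i], self._mW[i], self._vW[i]),
                (self.b[i], grads_b[i], self._mb[i], self._vb[i]),
            ):
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad**2
                param -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + eps)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        class_weight: np.ndarray | None = None,
    ) -> "FeedForwardClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_ = np.unique(np.concatenate([y, y_val]))
        n_classes = len(self.classes_)
        y_idx = np.searchsorted(self.classes_, y)
        yv_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        if class_weight is None:
            freq = np.bincount(y_idx, minlength=n_classes).astype(float)
            freq[freq == 0] = 1.0
            class_weight = len(y) / (n_classes * freq)
        class_weight = np.asarray(class_weight, dtype=np.float32)

        rng = np.random.default_rng(self.seed)
        self._init(X.shape[1], n_classes, rng)
        best_score, best_params, since_best = -np.inf, None, 0
        n = len(X)
        for _epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y_idx[idx]
                acts, p = self._forward(xb, rng=rng)
                w = class_weight[yb]
                delta = p.copy()
                delta[np.arange(len(yb)), yb] -= 1.0
                delta *= (w / w.sum())[:, None]
                grads_W, grads_b = [None] * len(self.W), [None] * len(self.b)
                for i in range(len(self.W) - 1, -1, -1):
                    grads_W[i] = acts[i].T @ delta + self.l2 * self.W[i]
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ self.W[i].T) * (acts[i] > 0)
                self._adam(grads_W, grads_b)
            score = balanced_accuracy(
                yv_idx, self._predict_idx(np.asarray(X_val, np.float32)), n_classes
            )
            if score > best_score + 1e-9:
                best_score = score
                best_params = (
                    [w.copy() for w in self.W],
                    [b.copy() for b in self.b],
                )
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_params is not None:
            self.W, self.b = best_params
        return self

    def _predict_idx(self, X: np.ndarray) -> np.ndarray:
        _, p = self._forward(X, rng=None)
        return np.argmax(p, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self._predict_idx(np.asarray(X, np.float32))]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, p = self._forward(np.asarray(X, np.float32), rng=None)
        return p
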