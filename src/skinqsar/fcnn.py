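"""Fully connected network for binary classification, implemented on NumPy.

Architecture (fixed shape, sizes tunable):

    input -> dense(h1) -> batchnorm -> ReLU -> dropout(p1)
          -> dense(h2) -> batchnorm -> ReLU -> dropout(p2)
          -> dense(1)  -> sigmoid

Training uses binary cross-entropy, the Adam optimizer, mini-batches, and
early stopping on validation loss (the weights from the best validation
epoch are restored). Batch normalization keeps running mean/variance for
inference; dropout is inverted so inference needs no rescaling. Hidden
dense layers carry no bias — the batch-norm shift absorbs it.

All randomness (init, shuffling, dropout masks) flows from ``random_state``,
so a fit is bit-reproducible.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class EarlyStopping:
    """Stop when validation loss has not improved for ``patience`` epochs.

    ``update`` returns True when training should halt, i.e. after exactly
    ``patience`` consecutive non-improving epochs.
    """

    def __init__(self, patience: int = 20, min_delta: float = 0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = -1
        self.bad_epochs = 0
        self.n_seen = 0

    def update(self, loss: float) -> bool:
        epoch = self.n_seen
        self.n_seen += 1
        if loss < self.best_loss - self.min_delta:
            self.best_loss = loss
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_from_logits(z, y):
    # mean(softplus(z) - y*z), numerically stable
    return float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))


class FCNNClassifier(BaseEstimator, ClassifierMixin):
    """Two-hidden-layer feed-forward classifier with batchnorm and dropout.

    Parameters mirror the tuned search space: hidden sizes ``hidden1`` /
    ``hidden2``, dropout rates after each hidden block, Adam learning rate,
    batch size, epoch cap and early-stopping patience. When no explicit
    validation set is passed to :meth:`fit`, ``validation_fraction`` of the
    training data is carved out (stratified) for early stopping.
    """

    def __init__(
        self,
        hidden1: int = 512,
        hidden2: int = 128,
        dropout1: float = 0.3,
        dropout2: float = 0.3,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 20,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.dropout1 = dropout1
        self.dropout2 = dropout2
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _init_params(self, d, rng):
        h1, h2 = self.hidden1, self.hidden2
        self.W1_ = rng.normal(0, np.sqrt(2.0 / d), (d, h1))
        self.g1_, self.b1_ = np.ones(h1), np.zeros(h1)
        self.W2_ = rng.normal(0, np.sqrt(2.0 / h1), (h1, h2))
        self.g2_, self.b2_ = np.ones(h2), np.zeros(h2)
        self.W3_ = rng.normal(0, np.sqrt(2.0 / h2), (h2, 1))
        self.b3_ = np.zeros(1)
        self.rm1_, self.rv1_ = np.zeros(h1), np.ones(h1)
        self.rm2_, self.rv2_ = np.zeros(h2), np.ones(h2)

    def _params(self):
        return [self.W1_, self.g1_, self.b1_, self.W2_, self.g2_, self.b2_,
                self.W3_, self.b3_]

    def _snapshot(self):
        keys = ("W1_", "g1_", "b1_", "W2_", "g2_", "b2_", "W3_", "b3_",
                "rm1_", "rv1_", "rm2_", "rv2_")
        return {k: getattr(self, k).copy() for k in keys}

    def _restore(self, snap):
        for k, v in snap.items():
            setattr(self, k, v.copy())

    def _forward_eval(self, X):
        s1 = X @ self.W1_
        a1 = np.maximum(self.g1_ * (s1 - self.rm1_) / np.sqrt(self.rv1_ + _BN_EPS)
                        + self.b1_, 0)
        s2 = a1 @ self.W2_
        a2 = np.maximum(self.g2_ * (s2 - self.rm2_) / np.sqrt(self.rv2_ + _BN_EPS)
                        + self.b2_, 0)
        return a2 @ self.W3_ + self.b3_   # logits, shape (n, 1)

    def _train_batch(self, X, y, adam, rng):
        n = X.shape[0]
        # layer 1
        s1 = X @ self.W1_
        mu1, var1 = s1.mean(0), s1.var(0)
        iv1 = 1.0 / np.sqrt(var1 + _BN_EPS)
        xh1 = (s1 - mu1) * iv1
        u1 = self.g1_ * xh1 + self.b1_
        a1 = np.maximum(u1, 0)
        m1 = (rng.random(a1.shape) >= self.dropout1) / (1 - self.dropout1)
        d1 = a1 * m1
        # layer 2
        s2 = d1 @ self.W2_
        mu2, var2 = s2.mean(0), s2.var(0)
        iv2 = 1.0 / np.sqrt(var2 + _BN_EPS)
        xh2 = (s2 - mu2) * iv2
        u2 = self.g2_ * xh2 + self.b2_
        a2 = np.maximum(u2, 0)
        m2 = (rng.random(a2.shape) >= self.dropout2) / (1 - self.dropout2)
        d2 = a2 * m2
        # head
        z = d2 @ self.W3_ + self.b3_
        p = _sigmoid(z)
        loss = _bce_from_logits(z, y)

        dz = (p - y) / n
        dW3 = d2.T @ dz
        db3 = dz.sum(0)
        dd2 = dz @ self.W3_.T
        da2 = dd2 * m2
        du2 = da2 * (u2 > 0)
        dg2 = (du2 * xh2).sum(0)
        db2 = du2.sum(0)
        dxh2 = du2 * self.g2_
        ds2 = (iv2 / n) * (n * dxh2 - dxh2.sum(0) - xh2 * (dxh2 * xh2).sum(0))
        dW2 = d1.T @ ds2
        dd1 = ds2 @ self.W2_.T
        da1 = dd1 * m1
        du1 = da1 * (u1 > 0)
        dg1 = (du1 * xh1).sum(0)
        db1 = du1.sum(0)
        dxh1 = du1 * self.g1_
        ds1 = (iv1 / n) * (n * dxh1 - dxh1.sum(0) - xh1 * (dxh1 * xh1).sum(0))
        dW1 = X.T @ ds1

        adam.step(self._params(),
                  [dW1, dg1, db1, dW2, dg2, db2, dW3, db3])
        # running stats (after the gradient step, standard practice)
        self.rm1_ = _BN_MOMENTUM * self.rm1_ + (1 - _BN_MOMENTUM) * mu1
        self.rv1_ = _BN_MOMENTUM * self.rv1_ + (1 - _BN_MOMENTUM) * var1
        self.rm2_ = _BN_MOMENTUM * self.rm2_ + (1 - _BN_MOMENTUM) * mu2
        self.rv2_ = _BN_MOMENTUM * self.rv2_ + (1 - _BN_MOMENTUM) * var2
        return loss

    # -- public API --------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(-1, 1)
        if X_val is None and self.validation_fraction > 0 and len(X) >= 20:
            X, X_val, y, y_val = train_test_split(
                X, y, test_size=self.validation_fraction,
                stratify=y, random_state=self.random_state)
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self._init_params(X.shape[1], rng)
        adam = _Adam([p.shape for p in self._params()], self.learning_rate)

        n = X.shape[0]
        stopper = EarlyStopping(self.patience) if X_val is not None else None
        best = None
        self.loss_curve_, self.val_loss_curve_ = [], []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                if batch.size < 2:   # batchnorm needs >= 2 rows
                    continue
                losses.append(self._train_batch(X[batch], y[batch], adam, rng))
            if not losses or not np.all(np.isfinite(losses)):
                raise FloatingPointError("non-finite or empty training loss")
            self.loss_curve_.append(float(np.mean(losses)))
            if stopper is not None:
                val_loss = _bce_from_logits(
                    self._forward_eval(np.asarray(X_val, dtype=np.float64)),
                    np.asarray(y_val, dtype=np.float64).reshape(-1, 1))
                self.val_loss_curve_.append(val_loss)
                prev_best = stopper.best_loss
                stop = stopper.update(val_loss)
                if val_loss < prev_best:
                    best = self._snapshot()
                if stop:
                    break
        self.n_epochs_ = len(self.loss_curve_)
        if best is not None:
            self._restore(best)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        p1 = _sigmoid(self._forward_eval(X)).ravel()
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
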