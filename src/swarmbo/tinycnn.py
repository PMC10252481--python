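"""A compact NumPy convolutional classifier for the tuning demo objective.

This realizes the configuration→architecture mapping of the benchmark: a
two-block network whose first block has a small fixed width while the
second block takes its feature-map count, kernel size, activation and
pooling window from the configuration, followed by dropout and a softmax
head over the six visual-field classes.  The optimizer family, learning
rate, batch size and (budget-scaled) epoch count also come from the
configuration, and the two boolean flags toggle trainability of the second
(upper) and first (lower) convolutional block after a brief seeded
pre-training pass on a synthetic source task.

Convolutions use im2col/col2im with valid padding; the four optimizer
update rules (SGD, Adam, RMSprop, Adadelta) are implemented directly.  The
network is deliberately small — it exists to make hyperparameter tuning
runs measurable in seconds-to-minutes on a CPU, not to approach the
reference models' accuracy.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .space import Configuration
from .synthbench import VFDataset, VF_CLASSES

__all__ = ["TinyCNN", "train_and_score"]

FIXED_BLOCK1_WIDTH = 4
MAX_EPOCHS = 20
CHANCE = 100.0 / len(VF_CLASSES)


def _im2col(X: np.ndarray, k: int) -> np.ndarray:
    # X: (N, C, H, W) -> (N, H'*W', C*k*k), valid padding, stride 1
    win = sliding_window_view(X, (k, k), axis=(2, 3))      # (N,C,H',W',k,k)
    N, C, Ho, Wo = win.shape[:4]
    return (win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, C * k * k),
            Ho, Wo)


def _col2im(dcols: np.ndarray, shape, k: int, Ho: int, Wo: int) -> np.ndarray:
    N, C, H, W = shape
    dX = np.zeros((N, C, H, W))
    dcols = dcols.reshape(N, Ho, Wo, C, k, k)
    for a in range(k):
        for b in range(k):
            dX[:, :, a:a + Ho, b:b + Wo] += dcols[:, :, :, :, a, b].transpose(
                0, 3, 1, 2)
    return dX


def _activate(z, name):
    if name == "ReLU":
        return np.maximum(z, 0.0)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))   # Sigmoid


def _activate_grad(z, name):
    if name == "ReLU":
        return (z > 0).astype(float)
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return s * (1.0 - s)


class _Optimizer:
    """Per-parameter state for SGD / Adam / RMSprop / Adadelta updates."""

    def __init__(self, name: str, lr: float):
        self.name, self.lr, self.state, self.t = name, lr, {}, 0

    def update(self, key: str, param: np.ndarray, grad: np.ndarray) -> None:
        s = self.state.setdefault(key, {"m": np.zeros_like(param),
                                        "v": np.zeros_like(param),
                                        "u": np.zeros_like(param)})
        if self.name == "SGD":
            param -= self.lr * grad
        elif self.name == "ADAM":
            b1, b2, eps = 0.9, 0.999, 1e-8
            s["m"] = b1 * s["m"] + (1 - b1) * grad
            s["v"] = b2 * s["v"] + (1 - b2) * grad ** 2
            mhat = s["m"] / (1 - b1 ** self.t)
            vhat = s["v"] / (1 - b2 ** self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + eps)
        elif self.name == "RMSprop":
            rho, eps = 0.9, 1e-8
            s["v"] = rho * s["v"] + (1 - rho) * grad ** 2
            param -= self.lr * grad / (np.sqrt(s["v"]) + eps)
        elif self.name == "Adadelta":
            rho, eps = 0.95, 1e-6
            s["v"] = rho * s["v"] + (1 - rho) * grad ** 2
            step = (np.sqrt(s["u"] + eps) / np.sqrt(s["v"] + eps)) * grad
            s["u"] = rho * s["u"] + (1 - rho) * step ** 2
            param -= step                      # Adadelta ignores lr by design
        else:
            raise ValueError(f"unknown optimizer {self.name!r}")

    def begin_step(self):
        self.t += 1


class TinyCNN:
    """Two conv blocks + dropout + softmax head, pure NumPy."""

    def __init__(self, feature_map: int, filter_size: int, activation: str,
                 pool_size: int, dropout_rate: float, n_classes: int,
                 image_size: int, seed: int):
        rng = np.random.default_rng(seed)
        self.activation = activation
        self.pool1 = 2
        self.pool2 = max(1, int(pool_size))
        self.k1, self.k2 = 3, max(1, int(filter_size))
        self.dropout = float(dropout_rate)
        c1, c2 = FIXED_BLOCK1_WIDTH, int(feature_map)
        self.W1 = rng.normal(0, np.sqrt(2.0 / (self.k1 ** 2)), (c1, self.k1 ** 2))
        self.b1 = np.zeros(c1)
        self.W2 = rng.normal(0, np.sqrt(2.0 / (c1 * self.k2 ** 2)),
                             (c2, c1 * self.k2 ** 2))
        self.b2 = np.zeros(c2)
        h = image_size - self.k1 + 1
        h = h // self.pool1
        h = h - self.k2 + 1
        h = h // self.pool2
        if h < 1:
            raise ValueError("image too small for this architecture")
        self.feat_dim = c2 * h * h
        self.Wd = rng.normal(0, np.sqrt(1.0 / self.feat_dim),
                             (n_classes, self.feat_dim))
        self.bd = np.zeros(n_classes)
        self.train_block1 = True
        self.train_block2 = True
        self._rng = rng

    # -- head management (transfer-style reuse of the conv stack) ----------

    def reset_head(self, n_classes: int) -> None:
        self.Wd = self._rng.normal(0, np.sqrt(1.0 / self.feat_dim),
                                   (n_classes, self.feat_dim))
        self.bd = np.zeros(n_classes)

    # -- forward / backward -------------------------------------------------

    def _pool(self, X, p):
        if p == 1:
            return X, None
        N, C, H, W = X.shape
        Hc, Wc = (H // p) * p, (W // p) * p
        Xc = X[:, :, :Hc, :Wc].reshape(N, C, Hc // p, p, Wc // p, p)
        out = Xc.max(axis=(3, 5))
        mask = (Xc == out[:, :, :, None, :, None])
        return out, (mask, (N, C, H, W, Hc, Wc))

    def _pool_back(self, dout, cache, p):
        if p == 1:
            return dout
        mask, (N, C, H, W, Hc, Wc) = cache
        dX = np.zeros((N, C, H, W))
        expanded = mask * dout[:, :, :, None, :, None]
        dX[:, :, :Hc, :Wc] = expanded.reshape(N, C, Hc, Wc)
        return dX

    def forward(self, X: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        cache = {}
        X = X[:, None, :, :]                     # (N, 1, H, W)
        cols1, Ho, Wo = _im2col(X, self.k1)
        z1 = cols1 @ self.W1.T + self.b1
        a1 = _activate(z1, self.activation)
        A1 = a1.transpose(0, 2, 1).reshape(len(X), -1, Ho, Wo)
        P1, pc1 = self._pool(A1, self.pool1)
        cols2, Ho2, Wo2 = _im2col(P1, self.k2)
        z2 = cols2 @ self.W2.T + self.b2
        a2 = _activate(z2, self.activation)
        A2 = a2.transpose(0, 2, 1).reshape(len(X), -1, Ho2, Wo2)
        P2, pc2 = self._pool(A2, self.pool2)
        feats = P2.reshape(len(X), -1)
        if train and self.dropout > 0:
            keep = (rng.random(feats.shape) >= self.dropout)
            feats = feats * keep / (1.0 - self.dropout)
            cache["keep"] = keep
        logits = feats @ self.Wd.T + self.bd
        cache.update(X=X, cols1=cols1, z1=z1, P1=P1, pc1=pc1, HoWo=(Ho, Wo),
                     cols2=cols2, z2=z2, pc2=pc2, HoWo2=(Ho2, Wo2),
                     feats=feats, P2shape=P2.shape)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache, opt: _Optimizer) -> None:
        N = len(dlogits)
        feats = cache["feats"]
        dWd = dlogits.T @ feats / N
        dbd = dlogits.mean(axis=0)
        dfeats = dlogits @ self.Wd
        if "keep" in cache:
            dfeats = dfeats * cache["keep"] / (1.0 - self.dropout)
        dP2 = dfeats.reshape(cache["P2shape"])
        dA2 = self._pool_back(dP2, cache["pc2"], self.pool2)
        Ho2, Wo2 = cache["HoWo2"]
        da2 = dA2.reshape(N, -1, Ho2 * Wo2).transpose(0, 2, 1)
        dz2 = da2 * _activate_grad(cache["z2"], self.activation)
        opt.begin_step()
        opt.update("Wd", self.Wd, dWd)
        opt.update("bd", self.bd, dbd)
        if self.train_block2:
            dW2 = np.einsum("npf,npc->fc", dz2, cache["cols2"]) / N
            opt.update("W2", self.W2, dW2)
            opt.update("b2", self.b2, dz2.mean(axis=(0, 1)) * dz2.shape[1])
        if self.train_block1:
            dcols2 = dz2 @ self.W2
            dP1 = _col2im(dcols2, cache["P1"].shape, self.k2, Ho2, Wo2)
            dA1 = self._pool_back(dP1, cache["pc1"], self.pool1)
            Ho, Wo = cache["HoWo"]
            da1 = dA1.reshape(N, -1, Ho * Wo).transpose(0, 2, 1)
            dz1 = da1 * _activate_grad(cache["z1"], self.activation)
            dW1 = np.einsum("npf,npc->fc", dz1, cache["cols1"]) / N
            opt.update("W1", self.W1, dW1)
            opt.update("b1", self.b1, dz1.mean(axis=(0, 1)) * dz1.shape[1])

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int, batch_size: int,
            optimizer: str, learning_rate: float,
            rng: np.random.Generator) -> bool:
        """Mini-batch training; returns False if the loss went non-finite."""
        opt = _Optimizer(optimizer, learning_rate)
        n = len(X)
        n_classes = self.Wd.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                logits, cache = self.forward(X[idx], train=True, rng=rng)
                logits = logits - logits.max(axis=1, keepdims=True)
                expz = np.exp(logits)
                probs = expz / expz.sum(axis=1, keepdims=True)
                if not np.isfinite(probs).all():
                    return False
                onehot = np.eye(n_classes)[y[idx]]
                self.backward(probs - onehot, cache, opt)
                for arr in (self.W1, self.W2, self.Wd):
                    if not np.isfinite(arr).all():
                        return False
        return True

    def predict(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for start in range(0, len(X), batch):
            logits, _ = self.forward(X[start:start + batch], train=False)
            out.append(np.argmax(logits, axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


def _source_task(n: int, size: int, rng: np.random.Generator):
    """Synthetic 4-class pre-training task: which quadrant is bright."""
    X = rng.normal(0.4, 0.05, (n, size, size))
    y = rng.integers(4, size=n)
    half = size // 2
    for i, q in enumerate(y):
        r0 = 0 if q in (0, 1) else half
        c0 = 0 if q in (0, 2) else half
        X[i, r0:r0 + half, c0:c0 + half] += 0.4
    return np.clip(X, 0.0, 1.0), y


def train_and_score(config: Configuration, data: VFDataset,
                    budget_scale: float = 0.1, seed: int = 0,
                    pretrain_steps: int = 30) -> float:
    """Build, (pre)train and score the configured network.

    Returns validation accuracy in percent; a training collapse to
    non-finite loss returns the 6-class chance level with a warning.
    """
    label_idx = {c: i for i, c in enumerate(VF_CLASSES)}
    train = data.subset("train")
    val = data.subset("val")
    size = data.images.shape[1]
    rng = np.random.default_rng(seed)
    net = TinyCNN(feature_map=config["feature_map"],
                  filter_size=config["filter_size"],
                  activation=config["activation"],
                  pool_size=config["pool_size"],
                  dropout_rate=config["dropout_rate"],
                  n_classes=len(VF_CLASSES), image_size=size, seed=seed)

    if pretrain_steps > 0:
        Xs, ys = _source_task(pretrain_steps * 8, size, rng)
        net.reset_head(4)
        net.fit(Xs, ys, epochs=1, batch_size=8,
                optimizer="SGD", learning_rate=0.01, rng=rng)
        net.reset_head(len(VF_CLASSES))

    # the boolean flags decide which blocks stay trainable for fine-tuning
    net.train_block2 = str(config["upper_layer"]).upper() == "TRUE"
    net.train_block1 = str(config["lower_layer"]).upper() == "TRUE"

    epochs = min(MAX_EPOCHS, int(round(config["epoch"] * budget_scale)))
    ok = True
    if epochs > 0 and len(train) > 0:
        ytr = np.array([label_idx[l] for l in train.labels])
        ok = net.fit(train.images, ytr, epochs=epochs,
                     batch_size=int(config["batch_size"]),
                     optimizer=config["optimizer"],
                     learning_rate=float(config["learning_rate"]), rng=rng)
    if not ok:
        warnings.warn("training diverged to non-finite loss; returning the "
                      "6-class chance level", stacklevel=2)
        return CHANCE
    yval = np.array([label_idx[l] for l in val.labels])
    pred = net.predict(val.images)
    if len(yval) == 0:
        return CHANCE
    return float(100.0 * np.mean(pred == yval))
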