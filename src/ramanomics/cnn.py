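"""A small 1-D convolutional network for spectral feature vectors.

Pure-NumPy implementation with explicit forward/backward passes: one or
two convolution blocks (width-7 kernels, ReLU, max-pool of 2; the
second block doubles the channel count), a dense ReLU layer and a
softmax output, trained with Adam on cross-entropy.  Inputs are
standardized internally (principal-component scores span orders of
magnitude in variance, which would otherwise dominate early training).
Weight initialization, batch shuffling and therefore the fitted model
are fully determined by ``seed``.

The class follows the scikit-learn estimator protocol closely enough
(``get_params`` / ``set_params`` / ``fit`` / ``predict_proba`` /
``predict``) to be driven by the same grid-search loop as the other
classifiers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Conv1DClassifier:
    """1D-CNN binary classifier on fixed-length feature vectors."""

    def __init__(self, n_conv_layers: int = 2, n_kernels: int = 16,
                 kernel_width: int = 7, dense_units: int = 64,
                 epochs: int = 60, batch_size: int = 32, lr: float = 1e-2,
                 patience: int = 10, seed: int = 0):
        self.n_conv_layers = n_conv_layers
        self.n_kernels = n_kernels
        self.kernel_width = kernel_width
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.seed = seed

    # -- scikit-learn estimator protocol ---------------------------------
    _param_names = ("n_conv_layers", "n_kernels", "kernel_width", "dense_units",
                    "epochs", "batch_size", "lr", "patience", "seed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "Conv1DClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- architecture ------------------------------------------------------
    def _init_weights(self, n_features: int, rng: np.random.Generator) -> dict:
        params: dict[str, np.ndarray] = {}
        c_in, length = 1, n_features
        for layer in range(self.n_conv_layers):
            c_out = self.n_kernels * (2 ** layer)
            fan_in = self.kernel_width * c_in
            params[f"W{layer}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                             size=(self.kernel_width, c_in, c_out))
            params[f"b{layer}"] = np.zeros(c_out)
            c_in = c_out
            length = length // 2  # max-pool 2
            if length < 1:
                raise ValueError("input too short for the configured conv/pool stack")
        flat = length * c_in
        params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, self.dense_units))
        params["bd"] = np.zeros(self.dense_units)
        params["Wo"] = rng.normal(0.0, np.sqrt(2.0 / self.dense_units),
                                  size=(self.dense_units, 2))
        params["bo"] = np.zeros(2)
        return params

    @staticmethod
    def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
        """'same'-padded stride-1 convolution. x: (N, L, C_in) -> (N, L, C_out)."""
        w = W.shape[0]
        pl, pr = (w - 1) // 2, w // 2
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        windows = sliding_window_view(xp, w, axis=1)      # (N, L, C_in, w)
        out = np.einsum("nlcw,wco->nlo", windows, W, optimize=True) + b
        return out, (xp, windows, pl)

    @staticmethod
    def _conv_backward(dout: np.ndarray, W: np.ndarray, cache):
        xp, windows, pl = cache
        w = W.shape[0]
        dW = np.einsum("nlcw,nlo->wco", windows, dout, optimize=True)
        db = dout.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        L = dout.shape[1]
        for k in range(w):
            dxp[:, k:k + L, :] += np.einsum("nlo,co->nlc", dout, W[k], optimize=True)
        dx = dxp[:, pl:pl + L, :]
        return dx, dW, db

    @staticmethod
    def _pool_forward(x: np.ndarray):
        n, L, c = x.shape
        L2 = L // 2
        pairs = x[:, :2 * L2, :].reshape(n, L2, 2, c)
        arg = pairs.argmax(axis=2)
        out = pairs.max(axis=2)
        return out, (arg, x.shape)

    @staticmethod
    def _pool_backward(dout: np.ndarray, cache):
        arg, shape = cache
        n, L, c = shape
        L2 = dout.shape[1]
        dpairs = np.zeros((n, L2, 2, c))
        np.put_along_axis(dpairs, arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(shape)
        dx[:, :2 * L2, :] = dpairs.reshape(n, 2 * L2, c)
        return dx

    def _forward(self, X: np.ndarray, params: dict):
        caches = []
        h = X[:, :, None]
        for layer in range(self.n_conv_layers):
            z, conv_cache = self._conv_forward(h, params[f"W{layer}"], params[f"b{layer}"])
            a = _relu(z)
            p, pool_cache = self._pool_forward(a)
            caches.append((conv_cache, z, pool_cache))
            h = p
        flat = h.reshape(h.shape[0], -1)
        zd = flat @ params["Wd"] + params["bd"]
        ad = _relu(zd)
        zo = ad @ params["Wo"] + params["bo"]
        proba = _softmax(zo)
        return proba, (caches, h.shape, flat, zd, ad)

    def _backward(self, X, y_onehot, proba, cache, params):
        caches, h_shape, flat, zd, ad = cache
        n = X.shape[0]
        grads: dict[str, np.ndarray] = {}
        dzo = (proba - y_onehot) / n
        grads["Wo"] = ad.T @ dzo
        grads["bo"] = dzo.sum(axis=0)
        dad = dzo @ params["Wo"].T
        dzd = dad * (zd > 0)
        grads["Wd"] = flat.T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dh = (dzd @ params["Wd"].T).reshape(h_shape)
        for layer in range(self.n_conv_layers - 1, -1, -1):
            conv_cache, z, pool_cache = caches[layer]
            da = self._pool_backward(dh, pool_cache)
            dz = da * (z > 0)
            dh, dW, db = self._conv_backward(dz, params[f"W{layer}"], conv_cache)
            grads[f"W{layer}"] = dW
            grads[f"b{layer}"] = db
        return grads

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None, y_val: np.ndarray | None = None) -> "Conv1DClassifier":
        """Train with Adam; early-stop on validation loss when provided.

        ``y`` holds integer class codes {0, 1}.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        self.mu_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        Xs = (X - self.mu_) / self.sd_
        params = self._init_weights(X.shape[1], rng)
        opt = _Adam(params, self.lr)
        onehot = np.eye(2)[y]
        monitor_X, monitor_y = (X_val, y_val) if X_val is not None else (None, None)
        best_loss, best_params, since_best = np.inf, None, 0
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                proba, cache = self._forward(Xs[sel], params)
                grads = self._backward(Xs[sel], onehot[sel], proba, cache, params)
                opt.step(params, grads)
            if monitor_X is not None:
                loss = self._loss(monitor_X, monitor_y, params)
            else:
                loss = self._loss(X, y, params)
            if loss < best_loss - 1e-6:
                best_loss, since_best = loss, 0
                best_params = {k: v.copy() for k, v in params.items()}
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.params_ = best_params if best_params is not None else params
        return self

    def _loss(self, X, y, params) -> float:
        Xs = (np.asarray(X, dtype=float) - self.mu_) / self.sd_
        proba, _ = self._forward(Xs, params)
        p = np.clip(proba[np.arange(len(y)), np.asarray(y, dtype=int)], 1e-12, 1.0)
        return float(-np.mean(np.log(p)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mu_) / self.sd_
        proba, _ = self._forward(Xs, self.params_)
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
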