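"""Small NumPy neural-network engine and the two sequence classifiers.

Implements exactly what the decoding analyses need — 1-D valid
convolution, ReLU, max-pooling, dense layers, an LSTM, softmax
cross-entropy and the Adam optimizer — with sklearn-style classifier
front-ends (fit/predict/predict_proba, trailing-underscore fitted
attributes) so they drop into the same cross-validation harness as the
SVMs.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# layers

class Dense:
    def __init__(self, n_in, n_out, rng):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.gW = self._x.T @ dy
        self.gb = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class Conv1d:
    """Valid 1-D convolution (cross-correlation), stride 1. x: (N, C, L)."""

    def __init__(self, c_in, c_out, k, rng):
        limit = np.sqrt(6.0 / (c_in * k + c_out * k))
        self.W = rng.uniform(-limit, limit, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x):
        k = self.k
        if x.shape[-1] < k:
            raise ValueError(f"input length {x.shape[-1]} < kernel size {k}")
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        self._win = win
        self._in_shape = x.shape
        return np.einsum("nclk,ock->nol", win, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, dy):
        k = self.k
        self.gW = np.einsum("nclk,nol->ock", self._win, dy, optimize=True)
        self.gb = dy.sum(axis=(0, 2))
        dy_p = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
        dwin = np.lib.stride_tricks.sliding_window_view(dy_p, k, axis=2)
        return np.einsum("nolk,ock->ncl", dwin, self.W[:, :, ::-1], optimize=True)

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class MaxPool1d:
    """Window 2, stride 2; a trailing odd sample is dropped."""

    def forward(self, x):
        n, c, L = x.shape
        L2 = L // 2
        xr = x[..., : 2 * L2].reshape(n, c, L2, 2)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, L = self._in_shape
        L2 = L // 2
        dx = np.zeros((n, c, L2, 2))
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=-1)
        out = np.zeros(self._in_shape)
        out[..., : 2 * L2] = dx.reshape(n, c, 2 * L2)
        return out

    def params(self):
        return []


class Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class LSTM:
    """Single LSTM layer returning the final hidden state. x: (N, C, L)."""

    def __init__(self, c_in, n_units, rng):
        H = n_units
        limit = np.sqrt(6.0 / (c_in + H + 4 * H))
        self.Wx = rng.uniform(-limit, limit, size=(c_in, 4 * H))
        self.Wh = rng.uniform(-limit, limit, size=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.H = H

    def forward(self, x):
        n, c, L = x.shape
        H = self.H
        h = np.zeros((n, H))
        cell = np.zeros((n, H))
        self._cache = []
        self._x = x
        for t in range(L):
            xt = x[:, :, t]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * cell + i * g
            tc = np.tanh(c_new)
            self._cache.append((xt, h, cell, i, f, g, o, tc))
            h = o * tc
            cell = c_new
        return h

    def backward(self, dh):
        n, c_in, L = self._x.shape
        H = self.H
        self.gWx = np.zeros_like(self.Wx)
        self.gWh = np.zeros_like(self.Wh)
        self.gb = np.zeros_like(self.b)
        dx = np.zeros_like(self._x)
        dc = np.zeros((n, H))
        for t in range(L - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            self.gWx += xt.T @ dz
            self.gWh += h_prev.T @ dz
            self.gb += dz.sum(axis=0)
            dx[:, :, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx

    def params(self):
        return [("Wx", self), ("Wh", self), ("b", self)]


# ---------------------------------------------------------------------------
# loss and optimizer

def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(proba, y_idx):
    """Mean negative log-probability of the true class."""
    p = np.clip(proba[np.arange(len(y_idx)), y_idx], 1e-300, None)
    return float(-np.mean(np.log(p)))


def uniform_crossentropy(n_classes: int) -> float:
    """Loss of a classifier predicting the uniform distribution (-ln 1/K)."""
    proba = np.full((1, n_classes), 1.0 / n_classes)
    return cross_entropy(proba, np.array([0]))


def softmax_ce_grad(logits, y_idx):
    """(loss, dlogits) for softmax cross-entropy, mean over the batch."""
    p = softmax(logits)
    loss = cross_entropy(p, y_idx)
    d = p.copy()
    d[np.arange(len(y_idx)), y_idx] -= 1.0
    return loss, d / len(y_idx)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (attr_name, layer)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(l, a)) for a, l in params]
        self.v = [np.zeros_like(getattr(l, a)) for a, l in params]

    def step(self):
        self.t += 1
        for idx, (attr, layer) in enumerate(self.params):
            g = getattr(layer, "g" + attr)
            self.m[idx] = self.b1 * self.m[idx] + (1 - self.b1) * g
            self.v[idx] = self.b2 * self.v[idx] + (1 - self.b2) * g * g
            mhat = self.m[idx] / (1 - self.b1**self.t)
            vhat = self.v[idx] / (1 - self.b2**self.t)
            w = getattr(layer, attr)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# classifiers

class _SequenceClassifier(BaseEstimator, ClassifierMixin):
    """Shared minibatch-Adam training loop over (N, C, L) sequences."""

    def __init__(self, epochs=100, learning_rate=1e-3, beta1=0.9, beta2=0.999,
                 batch_size=32, random_state=0):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.random_state = random_state

    def _build(self, c_in, length, n_classes, rng):  # pragma: no cover
        raise NotImplementedError

    def _forward(self, x):
        for layer in self.layers_:
            x = layer.forward(x)
        return x

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, n_channels, n_samples)")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, c, L = X.shape
        rng = np.random.default_rng(self.random_state)
        self.layers_ = self._build(c, L, len(self.classes_), rng)
        params = [p for layer in self.layers_ for p in layer.params()]
        opt = Adam(params, lr=self.learning_rate, beta1=self.beta1, beta2=self.beta2)
        self.train_loss_curve_ = []
        self.val_loss_curve_ = []
        self.val_accuracy_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self._forward(X[idx])
                loss, dlogits = softmax_ce_grad(logits, y_idx[idx])
                grad = dlogits
                for layer in reversed(self.layers_):
                    grad = layer.backward(grad)
                opt.step()
                losses.append(loss)
            self.train_loss_curve_.append(float(np.mean(losses)))
            if validation_data is not None:
                Xv, yv = validation_data
                proba = self.predict_proba(np.asarray(Xv, dtype=float))
                yv_idx = np.searchsorted(self.classes_, np.asarray(yv))
                self.val_loss_curve_.append(cross_entropy(proba, yv_idx))
                self.val_accuracy_curve_.append(
                    float(np.mean(self.classes_[proba.argmax(axis=1)] == np.asarray(yv)))
                )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        out = []
        for start in range(0, len(X), 256):
            out.append(softmax(self._forward(X[start : start + 256])))
        return np.concatenate(out)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class CNNClassifier(_SequenceClassifier):
    """LeNet-style 1-D CNN: three conv/ReLU stages (max-pool after the
    first two), a 84-unit dense layer, then softmax outputs.

    Default filter counts and kernel sizes (6 kernels of 32 samples,
    16 of 16, 120 of 8) match the decoding analysis; they are
    parameters so short test sequences can use smaller stacks.
    """

    def __init__(self, epochs=100, learning_rate=1e-3, beta1=0.9, beta2=0.999,
                 batch_size=32, random_state=0,
                 conv_specs=((6, 32), (16, 16), (120, 8)), hidden=84):
        super().__init__(epochs, learning_rate, beta1, beta2, batch_size, random_state)
        self.conv_specs = conv_specs
        self.hidden = hidden

    def _build(self, c_in, length, n_classes, rng):
        layers = []
        c, L = c_in, length
        for stage, (c_out, k) in enumerate(self.conv_specs):
            if L < k:
                raise ValueError(
                    f"sequence length {length} too short for conv stack at stage {stage}"
                )
            layers += [Conv1d(c, c_out, k, rng), ReLU()]
            c, L = c_out, L - k + 1
            if stage < len(self.conv_specs) - 1:
                layers.append(MaxPool1d())
                L = L // 2
        layers += [Flatten(), Dense(c * L, self.hidden, rng), ReLU(),
                   Dense(self.hidden, n_classes, rng)]
        return layers


class LSTMClassifier(_SequenceClassifier):
    """LSTM (default 20 units) over the 6-channel sequence; the final
    hidden state feeds a dense softmax output layer."""

    def __init__(self, epochs=100, learning_rate=1e-3, beta1=0.9, beta2=0.999,
                 batch_size=32, random_state=0, n_units=20, stride=1):
        super().__init__(epochs, learning_rate, beta1, beta2, batch_size, random_state)
        self.n_units = n_units
        self.stride = stride  # optional temporal subsampling for speed

    def _build(self, c_in, length, n_classes, rng):
        return [_Strided(self.stride), LSTM(c_in, self.n_units, rng),
                Dense(self.n_units, n_classes, rng)]


class _Strided:
    """Temporal subsampling layer (identity when stride is 1)."""

    def __init__(self, stride):
        self.stride = max(int(stride), 1)

    def forward(self, x):
        self._shape = x.shape
        return x[:, :, :: self.stride]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        dx[:, :, :: self.stride] = dy
        return dx

    def params(self):
        return []
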