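"""A small convolutional network in plain numpy.

The classifier this package needs is deliberately tiny — an AlexNet-inspired
stack of two 5x5 convolutions (32 filters each, ReLU, 2x2 max-pooling) and
two fully-connected layers with dropout, trained with Adam on a softmax
cross-entropy loss. At 64x64 single-channel inputs and double-digit sample
counts this trains in seconds to minutes on one CPU core, so the network is
implemented directly on numpy: convolutions run as im2col matrix products,
their gradients as the transposed products plus a full correlation with the
spatially flipped kernels. Everything is float32 and driven by an explicit
`numpy.random.Generator`, which makes training bit-reproducible for a fixed
seed on a fixed platform.

The forward/backward algebra is checked against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*Ho*Wo, C*k*k) patch matrix, stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,Ho,Wo,k,k)
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, ho, wo)


class Conv2D:
    """Same-padded stride-1 convolution (cross-correlation) via im2col."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.k, self.pad = k, (k - 1) // 2
        self.in_ch, self.out_ch = in_ch, out_ch
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.W = (std * rng.standard_normal((in_ch * k * k, out_ch))).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols, (n, ho, wo) = _im2col(x, self.k, self.pad)
        y = self._cols @ self.W + self.b
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray):
        n, f, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, f)
        dW = self._cols.T @ dyf
        db = dyf.sum(axis=0)
        # dX = full correlation of dy with the flipped kernels
        Wk = self.W.reshape(self.in_ch, self.k, self.k, self.out_ch)
        Wflip = Wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.out_ch * self.k * self.k, self.in_ch)
        cols_dy, (n2, ho, wo) = _im2col(dy, self.k, self.k - 1 - self.pad)
        dx = (cols_dy @ Wflip).reshape(n2, ho, wo, self.in_ch).transpose(0, 3, 1, 2)
        self._cols = None
        return dx, [dW, db]


class MaxPool2:
    """2x2 max pooling, stride 2 (input sides must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        scat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(scat, self._idx[..., None], dy[..., None], axis=-1)
        dx = scat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = (std * rng.standard_normal((n_in, n_out))).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray):
        dW = self._x.T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx, [dW, db]


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
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
            g = g.astype(p.dtype)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ConvNet:
    """conv(5x5,F)-relu-pool - conv(5x5,F)-relu-pool - fc(H)+dropout-relu - fc(2)+dropout.

    Binary softmax classifier over single-channel square images. Dropout is
    applied at both fully-connected layers (on the flattened features and on
    the hidden activations), matching the "dropout in the first and second
    fully-connected layers" design.
    """

    def __init__(self, input_side: int = 64, conv_filters: int = 32,
                 conv_kernel: int = 5, fc_hidden: int = 256,
                 dropout_rate: float = 0.5, n_classes: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        if input_side % 4 != 0:
            raise ValueError("input side must be divisible by 4 (two 2x2 pools)")
        self.input_side = input_side
        self.conv1 = Conv2D(1, conv_filters, conv_kernel, rng)
        self.relu1 = ReLU()
        self.pool1 = MaxPool2()
        self.conv2 = Conv2D(conv_filters, conv_filters, conv_kernel, rng)
        self.relu2 = ReLU()
        self.pool2 = MaxPool2()
        feat = conv_filters * (input_side // 4) ** 2
        self.drop1 = Dropout(dropout_rate)
        self.fc1 = Dense(feat, fc_hidden, rng)
        self.relu3 = ReLU()
        self.drop2 = Dropout(dropout_rate)
        self.fc2 = Dense(fc_hidden, n_classes, rng)
        self._train_rng = np.random.default_rng(seed + 1)

    @property
    def params(self):
        return self.conv1.params + self.conv2.params + self.fc1.params + self.fc2.params

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        rng = self._train_rng
        h = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        h = self.pool2.forward(self.relu2.forward(self.conv2.forward(h)))
        self._feat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.drop1.forward(h, train, rng)
        h = self.relu3.forward(self.fc1.forward(h))
        h = self.drop2.forward(h, train, rng)
        return self.fc2.forward(h)

    def _backward(self, dz: np.ndarray) -> list[np.ndarray]:
        dh, g_fc2 = self.fc2.backward(dz)
        dh = self.drop2.backward(dh)
        dh = self.relu3.backward(dh)
        dh, g_fc1 = self.fc1.backward(dh)
        dh = self.drop1.backward(dh)
        dh = dh.reshape(self._feat_shape)
        dh = self.pool2.backward(dh)
        dh = self.relu2.backward(dh)
        dh, g_c2 = self.conv2.backward(dh)
        dh = self.pool1.backward(dh)
        dh = self.relu1.backward(dh)
        _, g_c1 = self.conv1.backward(dh)
        return g_c1 + g_c2 + g_fc1 + g_fc2

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True):
        """Mean softmax cross-entropy and parameter gradients for one batch."""
        logits = self._forward(x, train)
        p = softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
        dz = p.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
        return loss, self._backward(dz.astype(np.float32))

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int, batch_size: int,
            learning_rate: float, shuffle_seed: int = 0, verbose: bool = False):
        """Adam training loop; returns the per-epoch mean loss trace."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None, :, :]
        y = np.asarray(y, dtype=int)
        opt = Adam(self.params, lr=learning_rate)
        shuffle_rng = np.random.default_rng(shuffle_seed)
        trace = []
        for _ in range(epochs):
            order = shuffle_rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self.loss_and_grads(X[idx], y[idx], train=True)
                opt.step(grads)
                losses.append(loss)
            trace.append(float(np.mean(losses)))
        return trace

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class probabilities (n, 2), dropout disabled."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None, :, :]
        out = []
        for start in range(0, len(X), batch_size):
            logits = self._forward(X[start:start + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)
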