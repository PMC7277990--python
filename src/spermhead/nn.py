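"""Minimal NHWC convolutional-network engine.

Implements exactly the layer set the sperm-head classifier needs —
2-D convolution (``same`` padding, stride 1) via im2col, batch
normalization, LeakyReLU, 2x2 average pooling, global average pooling
and a dense softmax head — each with an explicit backward pass, plus
Adam with inverse-time learning-rate decay and LeCun-uniform
initialization.  All tensors are float32, layout ``(N, H, W, C)``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def lecun_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Uniform(-limit, limit) with limit = sqrt(3 / fan_in)."""
    limit = np.sqrt(3.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base layer: children fill ``params`` / ``grads`` dicts keyed alike."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, zero ``same`` padding, odd k only."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = kernel_size * kernel_size * in_channels
        # weights are stored flattened (k*k*Cin, Cout) ready for the im2col matmul;
        # LeCun-uniform applies to bias as well (zero-fan convention: fan_in of the bias
        # is taken as the layer fan_in).
        self.params["W"] = lecun_uniform(rng, (fan_in, out_channels), fan_in)
        self.params["b"] = lecun_uniform(rng, (out_channels,), fan_in)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k = self.kernel_size
        p = k // 2
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        else:
            xp = x
        # (N, H, W, k, k, C) windows -> (N*H*W, k*k*C)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win shape: (N, H, W, C, k, k) ; move C last for a contiguous matmul layout
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, k * k * c)
        out = cols @ self.params["W"] + self.params["b"]
        if training:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        k = self.kernel_size
        p = k // 2
        c = self.in_channels
        dyf = dy.reshape(n * h * w, self.out_channels)
        self.grads["W"] = self._cols.T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"].T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(DTYPE)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv.astype(DTYPE))
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dy.sum(axis=(0, 1, 2))
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 1, 2))
              - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)) / m) * inv
        return dx.astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.3) -> None:
        super().__init__()
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mask = x >= 0
        if training:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx


class AvgPool2x2(Layer):
    """2x2 average pooling, stride 2; a trailing odd row/column is dropped."""

    def __init__(self) -> None:
        super().__init__()
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        self._in_shape = x.shape
        return x[:, :2 * ho, :2 * wo, :].reshape(n, ho, 2, wo, 2, c).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        ho, wo = h // 2, w // 2
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, :2 * ho, :2 * wo, :] = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0
        return dx


class GlobalAvgPool(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._in_shape).astype(DTYPE)


class Dense(Layer):
    """Fully connected layer with optional L2 kernel penalty."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 l2: float = 0.0) -> None:
        super().__init__()
        self.l2 = l2
        self.params["W"] = lecun_uniform(rng, (in_features, out_features), in_features)
        self.params["b"] = lecun_uniform(rng, (out_features,), in_features)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx

    def l2_penalty(self) -> float:
        return float(self.l2 * np.sum(self.params["W"].astype(np.float64) ** 2))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    grad = ((p - onehot) / n).astype(DTYPE)
    return loss, grad


class Adam:
    """Adam with the Keras-style per-step inverse-time decay
    lr_t = lr0 / (1 + decay * t)."""

    def __init__(self, layers: list[Layer], lr: float = 5e-4, decay: float = 0.0,
                 beta_1: float = 0.9, beta_2: float = 0.999, eps: float = 1e-7) -> None:
        self.layers = [ly for ly in layers if ly.params]
        self.lr0 = lr
        self.decay = decay
        self.b1 = beta_1
        self.b2 = beta_2
        self.eps = eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    @property
    def current_lr(self) -> float:
        return self.lr0 / (1.0 + self.decay * self.t)

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for ly, m, v in zip(self.layers, self._m, self._v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * (g * g)
                p -= (lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)).astype(DTYPE)
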