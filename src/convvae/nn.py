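"""Minimal neural-network layer stack with explicit backpropagation.

Implements exactly the layers the VAE architectures need — Linear, valid
Conv1d, ConvTranspose1d, BatchNorm1d, ReLU, Dropout — plus the Adam
optimizer. Arrays are float64 throughout; gradients are accumulated into
per-layer ``grads`` dicts aligned with ``params``. Every ``backward`` is
validated against central finite differences in the test suite.

Conventions
-----------
* Sequence tensors are ``(N, C, L)`` — batch, channel, position.
* ``Flatten`` uses numpy C-order reshape, i.e. channel-major: the flat
  index is ``c * L + l`` (channel varies slowest). The decoder's
  ``Unflatten`` inverts it with the same order.
* Convolutions are "valid" (no padding): ``L_out = (L - K) // S + 1``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Linear",
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "Flatten",
    "Unflatten",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class: parameterized, differentiable transform."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.params["W"] = _kaiming_uniform(rng, (out_features, in_features), in_features)
        self.params["b"] = _kaiming_uniform(rng, (out_features,), in_features)
        self.zero_grad()

    def forward(self, x, training=True):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]


class Conv1d(Layer):
    """Valid 1D convolution, stride S, bias, no padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        if not (1 <= stride <= kernel):
            raise ValueError("require 1 <= stride <= kernel")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        self.params["W"] = _kaiming_uniform(rng, (out_channels, in_channels, kernel), fan_in)
        self.params["b"] = _kaiming_uniform(rng, (out_channels,), fan_in)
        self.zero_grad()

    def out_length(self, length: int) -> int:
        if length < self.kernel:
            raise ValueError(f"input length {length} < kernel {self.kernel}")
        return (length - self.kernel) // self.stride + 1

    def forward(self, x, training=True):
        K, S = self.kernel, self.stride
        # windows: (N, C_in, L_out, K)
        win = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)[:, :, ::S, :]
        self._win = win
        self._in_length = x.shape[2]
        out = np.einsum("nclk,ock->nol", win, self.params["W"], optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, dout):
        K, S = self.kernel, self.stride
        self.grads["W"] += np.einsum("nclk,nol->ock", self._win, dout, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2))
        n, _, l_out = dout.shape
        dx = np.zeros((n, self.in_channels, self._in_length))
        # dpatch[n, c, l, k] = sum_o dout[n, o, l] W[o, c, k]
        dpatch = np.einsum("nol,ock->nclk", dout, self.params["W"], optimize=True)
        for k in range(K):
            dx[:, :, k:k + (l_out - 1) * S + 1:S] += dpatch[:, :, :, k]
        return dx


class ConvTranspose1d(Layer):
    """Transposed (fractionally strided) 1D convolution: L_out = (L-1)*S + K."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        self.params["W"] = _kaiming_uniform(rng, (in_channels, out_channels, kernel), fan_in)
        self.params["b"] = _kaiming_uniform(rng, (out_channels,), fan_in)
        self.zero_grad()

    def out_length(self, length: int) -> int:
        return (length - 1) * self.stride + self.kernel

    def forward(self, x, training=True):
        K, S = self.kernel, self.stride
        n, _, l_in = x.shape
        self._x = x
        out = np.zeros((n, self.out_channels, self.out_length(l_in)))
        # contrib[n, o, l, k] = sum_c x[n, c, l] W[c, o, k]
        contrib = np.einsum("ncl,cok->nolk", x, self.params["W"], optimize=True)
        for k in range(K):
            out[:, :, k:k + (l_in - 1) * S + 1:S] += contrib[:, :, :, k]
        return out + self.params["b"][None, :, None]

    def backward(self, dout):
        K, S = self.kernel, self.stride
        # windows of dout aligned with input positions: (N, C_out, L_in, K)
        win = np.lib.stride_tricks.sliding_window_view(dout, K, axis=2)[:, :, ::S, :]
        self.grads["W"] += np.einsum("ncl,nolk->cok", self._x, win, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2))
        return np.einsum("nolk,cok->ncl", win, self.params["W"], optimize=True)


class BatchNorm1d(Layer):
    """Batch normalization over (N, F) features or (N, C, L) channels."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(num_features)
        self.params["beta"] = np.zeros(num_features)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.zero_grad()

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, training=True):
        axes, shp = self._axes(x), self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] if x.ndim == 2 else x.shape[0] * x.shape[2]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv_std.reshape(shp)
        self._cache = (xhat, inv_std, axes, shp, training)
        return self.params["gamma"].reshape(shp) * xhat + self.params["beta"].reshape(shp)

    def backward(self, dout):
        xhat, inv_std, axes, shp, training = self._cache
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        g = self.params["gamma"].reshape(shp)
        if not training:
            return dout * g * inv_std.reshape(shp)
        m = np.prod([dout.shape[a] for a in axes])
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=axes).reshape(shp)
              - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)) * inv_std.reshape(shp)
        return dx

    @property
    def n_params(self) -> int:
        # affine pair only; running statistics are not trainable
        return 2 * self.num_features


class ReLU(Layer):
    def forward(self, x, training=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, training=True):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    """(N, C, L) -> (N, C*L), channel-major."""

    def forward(self, x, training=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Unflatten(Layer):
    """(N, C*L) -> (N, C, L), inverse of Flatten."""

    def __init__(self, channels: int, length: int):
        super().__init__()
        self.channels = channels
        self.length = length

    def forward(self, x, training=True):
        return x.reshape(x.shape[0], self.channels, self.length)

    def backward(self, dout):
        return dout.reshape(dout.shape[0], -1)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=True):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def param_items(self):
        """Yield (layer, name, array, grad) over all trainable tensors."""
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.param_items()
            else:
                for name in layer.params:
                    yield layer, name, layer.params[name], layer.grads[name]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, param_items, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        # param_items: list of (layer, name) handles
        self.handles = list(param_items)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.handles]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for layer, name in self.handles:
            layer.grads[name] = np.zeros_like(layer.params[name])
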