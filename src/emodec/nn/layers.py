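"""Layers with explicit forward/backward passes.

Activations flow as ``(B, F, T, C)`` arrays: batch, feature maps, time
steps, channels.  Raw segments enter as one feature map: ``(B, 1, P, C)``.
Every layer caches what its backward pass needs during ``forward`` and
must therefore be used in strict forward-then-backward order.
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError


class Layer:
    """Base layer: parameter-free unless a subclass fills ``params``."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class TemporalConv(Layer):
    """Valid convolution along the time axis, shared across channels.

    Weight shape ``(f_out, f_in, kernel)``; output time length is
    ``T - kernel + 1``.  No bias (batch norm follows in both decoders).
    """

    def __init__(self, f_in: int, f_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan = f_in * kernel
        self.params = [glorot_uniform(rng, (f_out, f_in, kernel), fan, f_out * kernel)]
        self.grads = [np.zeros_like(self.params[0])]

    def forward(self, x, training, rng):
        W = self.params[0]
        t_out = x.shape[2] - self.kernel + 1
        if t_out < 1:
            raise ValidationError(
                f"time axis {x.shape[2]} shorter than kernel {self.kernel}"
            )
        self._x = x
        out = np.zeros((x.shape[0], W.shape[0], t_out, x.shape[3]))
        for i in range(self.kernel):
            out += np.einsum("bgtc,fg->bftc", x[:, :, i : i + t_out, :], W[:, :, i], optimize=True)
        return out

    def backward(self, grad):
        W = self.params[0]
        x = self._x
        t_out = grad.shape[2]
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for i in range(self.kernel):
            xs = x[:, :, i : i + t_out, :]
            dW[:, :, i] = np.einsum("bftc,bgtc->fg", grad, xs, optimize=True)
            dx[:, :, i : i + t_out, :] += np.einsum("bftc,fg->bgtc", grad, W[:, :, i], optimize=True)
        self.grads[0][...] = dW
        return dx


class SpatialConv(Layer):
    """Convolution over the full channel axis (kernel 1 x C).

    Mixes all C channels of each time step into f_out feature maps,
    collapsing the channel axis to length 1 -- the "spatial filter" of the
    decoder, analogous to a CSP projection.  Weight shape
    ``(f_out, f_in, C)``; no bias.
    """

    def __init__(self, f_in: int, f_out: int, n_channels: int, rng: np.random.Generator):
        super().__init__()
        fan = f_in * n_channels
        self.params = [glorot_uniform(rng, (f_out, f_in, n_channels), fan, f_out)]
        self.grads = [np.zeros_like(self.params[0])]

    def forward(self, x, training, rng):
        W = self.params[0]
        if x.shape[3] != W.shape[2]:
            raise ValidationError(f"expected {W.shape[2]} channels, got {x.shape[3]}")
        self._x = x
        out = np.einsum("bgtc,fgc->bft", x, W, optimize=True)
        return out[:, :, :, None]

    def backward(self, grad):
        g = grad[:, :, :, 0]
        self.grads[0][...] = np.einsum("bft,bgtc->fgc", g, self._x, optimize=True)
        return np.einsum("bft,fgc->bgtc", g, self.params[0], optimize=True)


class BatchNorm(Layer):
    """Per-feature-map batch normalisation over (batch, time, channel).

    Running statistics (momentum 0.1) are used at inference.
    """

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = [np.ones(n_features), np.zeros(n_features)]  # gamma, beta
        self.grads = [np.zeros(n_features), np.zeros(n_features)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x, training, rng):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1, 1)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) * self._inv_std.reshape(shape)
        self._training = training
        return self.params[0].reshape(shape) * self._xhat + self.params[1].reshape(shape)

    def backward(self, grad):
        shape = (1, -1, 1, 1)
        axes = (0, 2, 3)
        self.grads[0][...] = np.sum(grad * self._xhat, axis=axes)
        self.grads[1][...] = np.sum(grad, axis=axes)
        gamma = self.params[0].reshape(shape)
        if not self._training:
            return grad * gamma * self._inv_std.reshape(shape)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dxhat = grad * gamma
        return (
            self._inv_std.reshape(shape)
            / m
            * (
                m * dxhat
                - np.sum(dxhat, axis=axes).reshape(shape)
                - self._xhat * np.sum(dxhat * self._xhat, axis=axes).reshape(shape)
            )
        )


class Square(Layer):
    """x -> x^2; with the following average pool and log it computes a
    smoothed log-power, mimicking band-power feature extraction."""

    def forward(self, x, training, rng):
        self._x = x
        return x * x

    def backward(self, grad):
        return 2.0 * self._x * grad


class LogActivation(Layer):
    """x -> log(max(x, eps)); eps floors zero pooled power."""

    def __init__(self, eps: float = 1e-6):
        super().__init__()
        self.eps = eps

    def forward(self, x, training, rng):
        self._clipped = np.maximum(x, self.eps)
        self._mask = x > self.eps
        return np.log(self._clipped)

    def backward(self, grad):
        return grad * self._mask / self._clipped


class Elu(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training, rng):
        self._neg = x < 0
        self._expm1 = np.where(self._neg, np.expm1(np.minimum(x, 0.0)), 0.0)
        return np.where(self._neg, self.alpha * self._expm1, x)

    def backward(self, grad):
        return grad * np.where(self._neg, self.alpha * (self._expm1 + 1.0), 1.0)


class AvgPoolTime(Layer):
    """Average pooling over time: window ``pool``, stride ``stride``,
    floor mode (output length ``(T - pool)//stride + 1``)."""

    def __init__(self, pool: int, stride: int):
        super().__init__()
        self.pool = pool
        self.stride = stride

    def _t_out(self, t: int) -> int:
        t_out = (t - self.pool) // self.stride + 1
        if t_out < 1:
            raise ValidationError(f"time axis {t} shorter than pool window {self.pool}")
        return t_out

    def forward(self, x, training, rng):
        t_out = self._t_out(x.shape[2])
        self._in_shape = x.shape
        out = np.zeros((x.shape[0], x.shape[1], t_out, x.shape[3]))
        for i in range(self.pool):
            out += x[:, :, i : i + (t_out - 1) * self.stride + 1 : self.stride, :]
        return out / self.pool

    def backward(self, grad):
        dx = np.zeros(self._in_shape)
        t_out = grad.shape[2]
        g = grad / self.pool
        for i in range(self.pool):
            dx[:, :, i : i + (t_out - 1) * self.stride + 1 : self.stride, :] += g
        return dx


class MaxPoolTime(Layer):
    """Max pooling over time (floor mode), tracking argmax for backward."""

    def __init__(self, pool: int, stride: int):
        super().__init__()
        self.pool = pool
        self.stride = stride

    def forward(self, x, training, rng):
        t_out = (x.shape[2] - self.pool) // self.stride + 1
        if t_out < 1:
            raise ValidationError(f"time axis {x.shape[2]} shorter than pool window {self.pool}")
        self._in_shape = x.shape
        stacked = np.stack(
            [x[:, :, i : i + (t_out - 1) * self.stride + 1 : self.stride, :] for i in range(self.pool)],
            axis=0,
        )
        self._argmax = np.argmax(stacked, axis=0)
        return np.max(stacked, axis=0)

    def backward(self, grad):
        dx = np.zeros(self._in_shape)
        t_out = grad.shape[2]
        for i in range(self.pool):
            mask = self._argmax == i
            sl = dx[:, :, i : i + (t_out - 1) * self.stride + 1 : self.stride, :]
            sl += np.where(mask, grad, 0.0)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValidationError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    """Affine map to class scores; weight (out, in) plus bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = [glorot_uniform(rng, (n_out, n_in), n_in, n_out), np.zeros(n_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training, rng):
        if x.shape[1] != self.params[0].shape[1]:
            raise ValidationError(
                f"dense layer expects {self.params[0].shape[1]} inputs, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.params[0].T + self.params[1]

    def backward(self, grad):
        self.grads[0][...] = grad.T @ self._x
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.params[0]
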