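"""Sequential container, log-softmax/NLL loss, and the Adam optimiser."""

from __future__ import annotations

import numpy as np

from .layers import Layer


def log_softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def nll_loss_and_grad(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log likelihood of integer targets, and d(loss)/d(scores).

    Applied to raw class scores via an internal log-softmax, i.e. the
    standard cross-entropy formulation of "NLL loss on log-probabilities".
    """
    n = len(y)
    logp = log_softmax(scores)
    loss = -float(logp[np.arange(n), y].mean())
    grad = np.exp(logp)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Network:
    """A plain sequential network over :class:`~emodec.nn.layers.Layer`."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def state(self) -> list[np.ndarray]:
        arrays = [p for layer in self.layers for p in layer.params]
        for layer in self.layers:
            for name in ("running_mean", "running_var"):
                if hasattr(layer, name):
                    arrays.append(getattr(layer, name))
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state()
        if len(own) != len(arrays):
            raise ValueError(f"state has {len(arrays)} arrays, expected {len(own)}")
        for dst, src in zip(own, arrays):
            dst[...] = src


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, network: Network, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.network = network
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        pairs = list(network.parameters())
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(self.network.parameters()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
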