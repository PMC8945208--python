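"""Compact feedforward building blocks (numpy, reverse-mode by hand).

The encoders here are small (hundreds of inputs, two hidden layers), trained
for seconds on CPU, so a minimal dense MLP with explicit backprop and Adam
keeps the package dependency-light and fully deterministic under a seed.

Conventions: hidden layers are ReLU, the output layer is linear (sigmoid /
loss coupling is handled by the loss helpers, in logit space for stability).
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "bce_logits", "bce_logits_grad", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_logits(logits: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy of sigmoid(logits) against binary targets."""
    # softplus(x) - x*t, computed stably
    sp = np.logaddexp(0.0, logits)
    return float(np.mean(sp - logits * target))


def bce_logits_grad(logits: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d logits."""
    return (sigmoid(logits) - target) / logits.size


class MLP:
    """Dense net: ReLU hidden layers, linear output, He/Glorot init."""

    def __init__(self, layer_sizes: list[int], rng: np.random.Generator):
        self.sizes = list(layer_sizes)
        self.Ws: list[np.ndarray] = []
        self.bs: list[np.ndarray] = []
        n_layers = len(layer_sizes) - 1
        for i in range(n_layers):
            fan_in, fan_out = layer_sizes[i], layer_sizes[i + 1]
            scale = np.sqrt(2.0 / fan_in) if i < n_layers - 1 else np.sqrt(1.0 / fan_in)
            self.Ws.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.bs.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.Ws, self.bs):
            out.extend((W, b))
        return out

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns (output, cache of post-activation values per layer)."""
        h = X
        cache = [X]
        last = len(self.Ws) - 1
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            z = h @ W + b
            h = z if i == last else np.maximum(z, 0.0)
            cache.append(h)
        return h, cache

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(
        self, cache: list[np.ndarray], d_out: np.ndarray
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backprop ``d_out`` (grad w.r.t. output) through the net.

        Returns (grad w.r.t. input, flat grads aligned with :attr:`params`).
        """
        last = len(self.Ws) - 1
        gWs: list[np.ndarray | None] = [None] * len(self.Ws)
        gbs: list[np.ndarray | None] = [None] * len(self.Ws)
        d = d_out
        for i in range(last, -1, -1):
            dz = d if i == last else d * (cache[i + 1] > 0)
            gWs[i] = cache[i].T @ dz
            gbs[i] = dz.sum(axis=0)
            d = dz @ self.Ws[i].T
        grads: list[np.ndarray] = []
        for gW, gb in zip(gWs, gbs):
            grads.extend((gW, gb))
        return d, grads


class Adam:
    """Adam over a fixed list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
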