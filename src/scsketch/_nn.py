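"""Minimal feed-forward network primitives (NumPy, manual backprop).

Kept deliberately small: dense layers with ReLU hidden activations and a
linear output, inverted dropout on hidden layers, and an Adam optimizer.
Everything is deterministic given the generator passed in.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected network: widths[0] -> ... -> widths[-1].

    ReLU after every layer except the last (linear). Dropout, when
    ``dropout_rate > 0``, is applied to hidden activations during training
    only (inverted scaling, so inference needs no rescale).
    """

    def __init__(
        self,
        widths: list[int],
        rng: np.random.Generator,
        dropout_rate: float = 0.0,
    ) -> None:
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.widths = list(widths)
        self.dropout_rate = float(dropout_rate)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Return (output, cache) where cache feeds :meth:`backward`."""
        cache = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < last:
                a = np.maximum(z, 0.0)
                mask = None
                if train and self.dropout_rate > 0.0:
                    if rng is None:
                        raise ValueError("dropout during training needs an rng")
                    keep = 1.0 - self.dropout_rate
                    mask = (rng.random(a.shape) < keep) / keep
                    a = a * mask
                cache.append((h, z, mask))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        return h, cache

    def backward(
        self, grad_out: np.ndarray, cache: list
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Backprop ``grad_out`` through the cached forward pass.

        Returns (param gradients aligned with :attr:`params`, input gradient).
        """
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        g = grad_out
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            h_in, z, mask = cache[i]
            if i < last:
                if mask is not None:
                    g = g * mask
                g = g * (z > 0.0)
            gW[i] = h_in.T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return gW + gb, g


class Adam:
    """Adam over a list of parameter arrays, updated in place."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
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
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
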