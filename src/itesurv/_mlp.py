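"""Minimal feed-forward network with hand-derived backprop and Adam.

Kept deliberately small: dense layers, ReLU hidden activations, inverted
dropout, L2 on weights.  Everything is NumPy and seeded, so training is
bit-reproducible on one machine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """widths = hidden layer sizes; the final layer is linear to ``out_dim``.

    With ``widths == []`` this is a single linear map (or, if
    ``identity=True`` and shapes agree, the identity with no parameters).
    """

    def __init__(self, in_dim: int, widths, out_dim: int, rng: np.random.Generator,
                 identity: bool = False):
        self.identity = identity and not widths and in_dim == out_dim
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        if not self.identity:
            dims = [in_dim] + list(widths) + [out_dim]
            for a, b in zip(dims[:-1], dims[1:]):
                scale = np.sqrt(2.0 / a)
                self.weights.append(rng.normal(0.0, scale, size=(a, b)))
                self.biases.append(np.zeros(b))

    @property
    def out_dim(self) -> int:
        if self.identity:
            raise AttributeError
        return self.weights[-1].shape[1]

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        """Returns (output, cache).  Dropout applies to hidden activations
        only and only when a generator is supplied (training mode)."""
        if self.identity:
            return x, None
        cache = {"inputs": [], "masks": []}
        a = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            cache["inputs"].append(a)
            z = a @ w + b
            if i < last:
                a = np.maximum(z, 0.0)
                if dropout > 0.0 and rng is not None:
                    mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                    a = a * mask
                else:
                    mask = None
                cache["masks"].append((z, mask))
            else:
                a = z
        return a, cache

    def backward(self, cache, grad_out: np.ndarray):
        """Returns (grad_input, grad_weights, grad_biases)."""
        if self.identity:
            return grad_out, [], []
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        g = grad_out
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            a_in = cache["inputs"][i]
            gw[i] = a_in.T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
            if i > 0:
                z, mask = cache["masks"][i - 1]
                if mask is not None:
                    g = g * mask
                g = g * (z > 0.0)
        return g, gw, gb

    def params(self):
        return self.weights + self.biases

    def copy_params(self):
        return [p.copy() for p in self.params()]

    def set_params(self, values):
        for p, v in zip(self.params(), values):
            p[...] = v


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if g is None:
                continue
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
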