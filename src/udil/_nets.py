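"""Minimal fully-connected networks with manual backprop, plus Adam.

The networks here are deliberately small (a two-hidden-layer extractor and a
linear evidential head); forward caches and analytic gradients keep the
whole training loop in numpy and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """Fully-connected net with tanh activations.

    ``activate_last=True`` (feature extractors) applies tanh to the output
    layer as well, bounding the embedding cube; ``False`` (classification
    heads) leaves the output linear.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator, activate_last: bool = False):
        self.dims = list(dims)
        self.activate_last = activate_last
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns (output, cache of post-activation inputs per layer)."""
        cache = [np.asarray(x, dtype=float)]
        h = cache[0]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            linear_out = i == self.n_layers - 1 and not self.activate_last
            h = z if linear_out else np.tanh(z)
            cache.append(h)
        return h, cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(
        self, cache: list[np.ndarray], dout: np.ndarray
    ) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """Backprop dout (dL/d output) through the cached forward pass.

        Returns (dL/d input, per-layer (dW, db)) in layer order.
        """
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * self.n_layers  # type: ignore
        delta = np.asarray(dout, dtype=float)
        for i in range(self.n_layers - 1, -1, -1):
            h_in, h_out = cache[i], cache[i + 1]
            if i != self.n_layers - 1 or self.activate_last:
                delta = delta * (1.0 - h_out**2)  # tanh'
            grads[i] = (h_in.T @ delta, delta.sum(axis=0))
            delta = delta @ self.weights[i].T
        return delta, grads

    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_params(self, params: list[np.ndarray]) -> None:
        n = self.n_layers
        self.weights = [np.array(p, dtype=float) for p in params[:n]]
        self.biases = [np.array(p, dtype=float) for p in params[n:]]

    def clone(self) -> "MLP":
        other = MLP.__new__(MLP)
        other.dims = list(self.dims)
        other.activate_last = self.activate_last
        other.weights = [w.copy() for w in self.weights]
        other.biases = [b.copy() for b in self.biases]
        return other


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
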