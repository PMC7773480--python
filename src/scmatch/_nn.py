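"""Minimal feed-forward neural-net core used by the integration model.

The networks involved are tiny (two hidden layers, tens of units), so this
module implements exactly what they need and nothing more: dense layers with
ReLU, explicit backpropagation, the Adam optimizer, and spectral
normalization for discriminator layers.  Everything is float64 numpy and
fully deterministic given a seeded ``numpy.random.Generator``.

Conventions: inputs are ``(batch, features)`` row matrices; ``forward``
caches what ``backward`` needs; parameter gradients accumulate in ``gW`` /
``gb`` until ``zero_grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam", "softplus", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


class Dense:
    """Fully connected layer with optional ReLU and spectral normalization.

    Spectral normalization divides the weight matrix by an estimate of its
    largest singular value, maintained by one power-iteration step per
    training forward pass; the scale is treated as a constant in backward.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        activation: str | None = "relu",
        spectral_norm: bool = False,
    ):
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.spectral_norm = spectral_norm
        self._u = rng.normal(size=n_out) if spectral_norm else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._mask: np.ndarray | None = None
        self._W_eff: np.ndarray | None = None
        self._sigma: float = 1.0

    def _normalized_weight(self, train: bool) -> np.ndarray:
        if not self.spectral_norm:
            self._sigma = 1.0
            return self.W
        u = self._u
        if train:
            v = self.W @ u
            v /= np.linalg.norm(v) + 1e-12
            u = self.W.T @ v
            u /= np.linalg.norm(u) + 1e-12
            self._u = u
        v = self.W @ u
        sigma = float(np.linalg.norm(v)) + 1e-12
        self._sigma = sigma
        return self.W / sigma

    def effective_weight(self) -> np.ndarray:
        """Weight matrix as applied to inputs (spectral-normalized if set)."""
        return self._normalized_weight(train=False)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        W = self._normalized_weight(train)
        a = x @ W + self.b
        if self.activation == "relu":
            mask = a > 0
            out = a * mask
        else:
            mask = None
            out = a
        if train:
            self._x, self._mask, self._W_eff = x, mask, W
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before a training forward pass")
        g = grad_out * self._mask if self.activation == "relu" else grad_out
        self.gW += (self._x.T @ g) / self._sigma
        self.gb += g.sum(axis=0)
        return g @ self._W_eff.T

    def zero_grad(self) -> None:
        self.gW[...] = 0.0
        self.gb[...] = 0.0

    def parameters(self):
        yield self.W, self.gW
        yield self.b, self.gb


class MLP:
    """A stack of :class:`Dense` layers applied in order."""

    def __init__(
        self,
        sizes: list[int],
        rng: np.random.Generator,
        out_activation: str | None = None,
        spectral_norm: bool = False,
    ):
        self.layers = []
        for i in range(len(sizes) - 1):
            last = i == len(sizes) - 2
            self.layers.append(
                Dense(
                    sizes[i],
                    sizes[i + 1],
                    rng,
                    activation=out_activation if last else "relu",
                    spectral_norm=spectral_norm,
                )
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


class Adam:
    """Adam optimizer over the parameters of one or more networks."""

    def __init__(self, nets, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.nets = list(nets)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for net in self.nets for p, _ in net.parameters()]
        self._v = [np.zeros_like(p) for net in self.nets for p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        i = 0
        for net in self.nets:
            for p, g in net.parameters():
                m, v = self._m[i], self._v[i]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1

    def zero_grad(self) -> None:
        for net in self.nets:
            net.zero_grad()
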