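"""Small feed-forward building blocks and an Adam optimizer.

The networks here are deliberately tiny (two hidden layers of a few dozen
units): the whole point of learning a 2-D information-bottleneck space first
is that the downstream density model can stay small.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, linear

__all__ = ["Linear", "MLP", "Adam"]


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            # Glorot-style scaling keeps tanh nets in their active range
            bound = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.W, self.b)

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.data + self.b.data

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Small multilayer perceptron; optional zero-initialized output layer.

    tanh hidden units suit the bounded coupling-flow scale/translation nets;
    relu suits the encoder/decoder, whose push-forward densities must not
    develop saturation plateaus.
    """

    def __init__(self, sizes, rng: np.random.Generator, zero_init_last: bool = False,
                 activation: str = "tanh"):
        if activation not in ("tanh", "relu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.layers = []
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            self.layers.append(Linear(a, b, rng, zero_init=zero_init_last and last))

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            h = layer(x)
            x = h.tanh() if self.activation == "tanh" else h.relu()
        return self.layers[-1](x)

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers[:-1]:
            h = layer.forward_np(x)
            x = np.tanh(h) if self.activation == "tanh" else np.maximum(h, 0.0)
        return self.layers[-1].forward_np(x)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state_arrays(self):
        out = []
        for layer in self.layers:
            out.extend([layer.W.data, layer.b.data])
        return out

    def load_arrays(self, arrays):
        it = iter(arrays)
        for layer in self.layers:
            layer.W.data = np.asarray(next(it), dtype=float)
            layer.b.data = np.asarray(next(it), dtype=float)


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
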