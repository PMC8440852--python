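"""Neural-network building blocks on top of the autodiff engine.

Layers follow the Keras-like convention of channels-last 1-D feature maps
(batch, width, channels). Initialisation is Glorot-uniform from a
caller-supplied numpy Generator so a single seed reproduces a model.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, chanmax, concat, conv1d

__all__ = [
    "Dense",
    "Conv1D",
    "SpatialAttention",
    "Adam",
    "softmax",
    "dropout_mask",
]


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, shape))


class Dense:
    def __init__(self, rng, n_in: int, n_out: int, activation: str | None = None):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = Tensor(np.zeros(n_out))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W + self.b
        if self.activation == "elu":
            y = y.elu()
        elif self.activation == "tanh":
            y = y.tanh()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y

    @property
    def params(self):
        return [self.W, self.b]


class Conv1D:
    """Same-padded, stride-1 1-D convolution with odd kernel size."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int,
                 activation: str | None = "elu"):
        self.w = _glorot(rng, (kernel, c_in, c_out), kernel * c_in, kernel * c_out)
        self.b = Tensor(np.zeros(c_out))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = conv1d(x, self.w, self.b)
        if self.activation == "elu":
            y = y.elu()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y

    @property
    def params(self):
        return [self.w, self.b]


class SpatialAttention:
    """Per-position weighting of 1-D feature maps.

    Channel-wise average- and max-pooled maps are concatenated, convolved
    with a same-padded kernel (default size 3) and squashed by a sigmoid;
    the resulting map in (0, 1) multiplies every channel of the input.
    """

    #: initial conv bias; a positive value opens the sigmoid gate (~0.95) so
    #: stacked attention modules start near-transparent instead of damping
    #: activations by 0.5 per layer at initialization
    BIAS_INIT = 3.0

    def __init__(self, rng, kernel: int = 3):
        self.w = _glorot(rng, (kernel, 2, 1), kernel * 2, kernel)
        self.b = Tensor(np.full(1, self.BIAS_INIT))

    def attention_map(self, f: Tensor) -> Tensor:
        pooled = concat([f.mean(axis=-1, keepdims=True), chanmax(f)], axis=2)
        return conv1d(pooled, self.w, self.b).sigmoid()

    def __call__(self, f: Tensor) -> Tensor:
        return f * self.attention_map(f)

    @property
    def params(self):
        return [self.w, self.b]


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(t.data.max(axis=axis, keepdims=True), requires_grad=False)
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout_mask(rng: np.random.Generator, shape, rate: float) -> Tensor:
    """Inverted-dropout mask: zeros with probability `rate`, else 1/(1-rate)."""
    keep = rng.random(shape) >= rate
    return Tensor(keep / (1.0 - rate), requires_grad=False)


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
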