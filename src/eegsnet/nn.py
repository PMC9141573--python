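"""Neural-network building blocks on top of the autodiff engine.

Layers hold their parameters as :class:`~eegsnet._autodiff.Tensor` leaves with
``requires_grad=True``; initialisation is Glorot-uniform for convolution and
dense kernels, orthogonal for recurrent kernels, zeros for biases, all drawn
from a caller-supplied seeded generator so that model construction is fully
reproducible.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = ["Conv3x3", "BatchNorm2d", "Linear", "BiLSTM", "Adam", "clip_grad_norm"]

_DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    q = q if q.shape == (rows, cols) else q.T
    return q.astype(_DTYPE)


class Conv3x3:
    """3×3 stride-1 convolution with same padding."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.weight = Tensor(
            _glorot(rng, (out_ch, in_ch, 3, 3), in_ch * 9, out_ch * 9),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv3x3_same(self.weight, self.bias)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels, dtype=_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x: Tensor, training: bool, momentum: float = 0.1) -> Tensor:
        return x.batchnorm(
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training,
            momentum=momentum,
        )

    def reset_stats(self) -> None:
        self.running_mean[:] = 0.0
        self.running_var[:] = 0.0

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Linear:
    """Dense layer, ``y = x @ W + b``."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(
            _glorot(rng, (in_dim, out_dim), in_dim, out_dim), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_dim, dtype=_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class _LSTMDirection:
    """One direction of one LSTM layer (gate order i, f, g, o)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.w_ih = Tensor(
            _glorot(rng, (in_dim, 4 * hidden), in_dim, 4 * hidden), requires_grad=True
        )
        w_hh = np.concatenate(
            [_orthogonal(rng, hidden, hidden) for _ in range(4)], axis=1
        )
        self.w_hh = Tensor(w_hh, requires_grad=True)
        bias = np.zeros(4 * hidden, dtype=_DTYPE)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias: standard init
        self.bias = Tensor(bias, requires_grad=True)

    def run(self, xs: list[Tensor], reverse: bool) -> list[Tensor]:
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, self.hidden), dtype=_DTYPE))
        c = Tensor(np.zeros((batch, self.hidden), dtype=_DTYPE))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: dict[int, Tensor] = {}
        hd = self.hidden
        for t in order:
            z = xs[t] @ self.w_ih + h @ self.w_hh + self.bias
            i = z[:, 0 * hd : 1 * hd].sigmoid()
            f = z[:, 1 * hd : 2 * hd].sigmoid()
            g = z[:, 2 * hd : 3 * hd].tanh()
            o = z[:, 3 * hd : 4 * hd].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out[t] = h
        return [out[t] for t in range(len(xs))]

    def parameters(self) -> list[Tensor]:
        return [self.w_ih, self.w_hh, self.bias]


class BiLSTM:
    """Stacked bidirectional LSTM over a sequence of (batch, features) steps.

    Each layer runs a forward and a backward pass and concatenates the two
    hidden states per time step (2×hidden features feeding the next layer).
    """

    def __init__(self, in_dim: int, hidden: int, layers: int, rng: np.random.Generator):
        self.layers: list[tuple[_LSTMDirection, _LSTMDirection]] = []
        d = in_dim
        for _ in range(layers):
            fwd = _LSTMDirection(d, hidden, rng)
            bwd = _LSTMDirection(d, hidden, rng)
            self.layers.append((fwd, bwd))
            d = 2 * hidden
        self.out_dim = d if layers > 0 else in_dim

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        for fwd, bwd in self.layers:
            hf = fwd.run(xs, reverse=False)
            hb = bwd.run(xs, reverse=True)
            xs = [concat([a, b], axis=1) for a, b in zip(hf, hb)]
        return xs

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for fwd, bwd in self.layers:
            out += fwd.parameters() + bwd.parameters()
        return out


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimiser (β₁=0.9, β₂=0.999, ε=1e−8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
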