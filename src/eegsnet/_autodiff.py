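"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the operations the EEGSNet architecture needs: broadcasted
arithmetic, matmul, slicing/concat/reshape, reductions, sigmoid/tanh/GELU,
clamped log and softmax, "same"-padded 3×3 convolution, 2×2 max pooling with
ceil semantics, 3×3 stride-1 average pooling, batch normalisation and inverted
dropout.  Gradients are accumulated by topological sweep over the recorded
graph; correctness is pinned down by finite-difference checks in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "gelu_array"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape

        def backward(g):
            self._accum(g.reshape(src_shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        def backward(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accum(full)

        return self._make(self.data[key], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities ---------------------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), backward)

    def gelu(self) -> "Tensor":
        """Exact-erf GELU: x · Φ(x)."""
        x = self.data
        phi_cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def backward(g):
            self._accum(g * (phi_cdf + x * pdf))

        return self._make(x * phi_cdf, (self,), backward)

    def log_clamped(self, lo: float = 1e-12) -> "Tensor":
        """log of probabilities clamped to [lo, 1]; gradient zero where clamped."""
        clipped = np.clip(self.data, lo, 1.0)
        inside = (self.data >= lo) & (self.data <= 1.0)

        def backward(g):
            self._accum(g * inside / clipped)

        return self._make(np.log(clipped), (self,), backward)

    def softmax(self) -> "Tensor":
        """Softmax along the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=-1, keepdims=True)
            self._accum(p * (g - dot))

        return self._make(p, (self,), backward)

    # -- structured ops -------------------------------------------------------
    def conv3x3_same(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """3×3 stride-1 convolution with same padding.

        ``self``: (B, C, H, W); ``weight``: (O, C, 3, 3); ``bias``: (O,).
        """
        x = self.data
        b_, c, h, w = x.shape
        o = weight.data.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        shifts = [(i, j) for i in range(3) for j in range(3)]
        # sum of 9 shifted GEMMs: avoids materialising an im2col buffer
        y = np.empty((b_, o, h, w), dtype=x.dtype)
        y[:] = bias.data[None, :, None, None]
        for di, dj in shifts:
            # (b, c, h, w) × (o, c) contracted over c
            y += np.einsum(
                "bchw,oc->bohw",
                xp[:, :, di : di + h, dj : dj + w],
                weight.data[:, :, di, dj],
                optimize=True,
            )

        def backward(g):
            if weight.requires_grad:
                gw = np.empty_like(weight.data)
                for di, dj in shifts:
                    gw[:, :, di, dj] = np.einsum(
                        "bohw,bchw->oc",
                        g,
                        xp[:, :, di : di + h, dj : dj + w],
                        optimize=True,
                    )
                weight._accum(gw)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for di, dj in shifts:
                    gxp[:, :, di : di + h, dj : dj + w] += np.einsum(
                        "bohw,oc->bchw", g, weight.data[:, :, di, dj], optimize=True
                    )
                self._accum(gxp[:, :, 1:-1, 1:-1])

        return self._make(y, (self, weight, bias), backward)

    def maxpool2x2(self) -> "Tensor":
        """2×2 stride-2 max pooling with ceil handling of odd sizes."""
        x = self.data
        b_, c, h, w = x.shape
        h2, w2 = -(-h // 2) * 2, -(-w // 2) * 2
        if (h2, w2) == (h, w):
            xp = x
        else:
            xp = np.full((b_, c, h2, w2), -np.inf, dtype=x.dtype)
            xp[:, :, :h, :w] = x
        win = xp.reshape(b_, c, h2 // 2, 2, w2 // 2, 2)
        flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(b_, c, h2 // 2, w2 // 2, 4)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
            gp = (
                gflat.reshape(b_, c, h2 // 2, w2 // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(b_, c, h2, w2)
            )
            self._accum(gp[:, :, :h, :w])

        return self._make(y, (self,), backward)

    def avgpool3x3_same(self) -> "Tensor":
        """3×3 stride-1 average pooling, same padding, true-count normalisation."""
        x = self.data
        b_, c, h, w = x.shape
        count = np.zeros((h, w))
        acc = np.zeros_like(x)
        ones = np.ones((h, w))
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                s_r = slice(max(0, di), h + min(0, di))
                s_c = slice(max(0, dj), w + min(0, dj))
                d_r = slice(max(0, -di), h + min(0, -di))
                d_c = slice(max(0, -dj), w + min(0, -dj))
                acc[:, :, d_r, d_c] += x[:, :, s_r, s_c]
                count[d_r, d_c] += ones[s_r, s_c]
        y = acc / count

        def backward(g):
            gn = g / count
            gx = np.zeros_like(x)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    s_r = slice(max(0, di), h + min(0, di))
                    s_c = slice(max(0, dj), w + min(0, dj))
                    d_r = slice(max(0, -di), h + min(0, -di))
                    d_c = slice(max(0, -dj), w + min(0, -dj))
                    gx[:, :, s_r, s_c] += gn[:, :, d_r, d_c]
            self._accum(gx)

        return self._make(y, (self,), backward)

    def batchnorm(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        running_mean: np.ndarray,
        running_var: np.ndarray,
        training: bool,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ) -> "Tensor":
        """Per-channel batch normalisation on (B, C, H, W) tensors.

        In training mode uses batch statistics (and updates the running
        buffers in place); in evaluation mode uses the running buffers, so the
        forward pass is a pure function.
        """
        x = self.data
        axes = (0, 2, 3)
        shape = (1, -1, 1, 1)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var * n / max(n - 1, 1)
        else:
            mu, var = running_mean, running_var
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(shape)) * invstd.reshape(shape)
        y = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gxhat = g * gamma.data.reshape(shape)
                if training:
                    n = x.shape[0] * x.shape[2] * x.shape[3]
                    term1 = gxhat
                    term2 = gxhat.mean(axis=axes).reshape(shape)
                    term3 = xhat * (gxhat * xhat).mean(axis=axes).reshape(shape)
                    self._accum((term1 - term2 - term3) * invstd.reshape(shape))
                else:
                    self._accum(gxhat * invstd.reshape(shape))

        return self._make(y, (self, gamma, beta), backward)

    def dropout(self, keep_prob: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout: keep with probability ``keep_prob``, scale by 1/keep."""
        if not 0.0 < keep_prob <= 1.0:
            raise ValueError(f"keep_prob must be in (0, 1], got {keep_prob}")
        if keep_prob == 1.0:
            return self
        mask = (rng.random(self.data.shape) < keep_prob) / keep_prob

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- backward pass ---------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node; seeds with ones for scalars."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def gelu_array(x: np.ndarray | float):
    """Plain-array exact GELU, x · Φ(x), for use outside the graph."""
    x = np.asarray(x, dtype=np.float64)
    out = x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    return out if out.ndim else float(out)
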