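"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs the reverse sweep over the recorded graph.
The op set is exactly what the encoders, the transformer fusion module and
the training loop need: broadcast arithmetic, matmul, shape ops, reductions,
the activations used by the architectures, (grouped) 2-D convolution via
im2col, max pooling, softmax and a fused softmax cross-entropy.

All gradients are checked against central finite differences in the test
suite; keep new ops covered there.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d", "softmax", "cross_entropy_logits",
           "mac_counting"]

_DEFAULT_DTYPE = np.float32

# When set (by the `mac_counting` context manager), conv2d and matmul add
# their multiply-accumulate counts here.  Elementwise ops are not counted:
# published complexity tables follow the conv/matmul-only convention.
_MACS: list[int] | None = None


class mac_counting:
    """Context manager accumulating multiply-accumulate counts of conv/matmul."""

    def __enter__(self):
        global _MACS
        self._saved = _MACS
        _MACS = [0]
        return self

    def __exit__(self, *exc):
        global _MACS
        self.total = _MACS[0]
        _MACS = self._saved
        return False


def _as_array(x) -> np.ndarray:
    if isinstance(x, (np.ndarray, np.generic)):
        a = np.asarray(x)
        return a if a.dtype in (np.float32, np.float64) else a.astype(_DEFAULT_DTYPE)
    return np.asarray(x, dtype=_DEFAULT_DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(p for p in _prev if p.requires_grad)
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def _accum_index(self, idx, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[idx] += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many layers)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))
        out._backward = _bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        if _MACS is not None:
            _MACS[0] += int(np.prod(out.data.shape)) * self.data.shape[-1]

        def _bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = _bwd
        return out

    # ----------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = _bwd
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ elementwise
    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        x = self.data
        phi = np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
        Phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor((x * Phi).astype(x.dtype), self.requires_grad, (self,))
        dgelu = (Phi + x * phi).astype(x.dtype)
        out._backward = lambda g: self._accum(g * dgelu)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s.astype(self.data.dtype), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * (s * (1 - s)).astype(self.data.dtype))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * (1 - t * t))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * 0.5 / r)
        return out


# ---------------------------------------------------------------------- fused


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = _bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, x.requires_grad, (x,))

    def _bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))
    out._backward = _bwd
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer labels (nats)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    out = Tensor(np.asarray(nll, dtype=logits.data.dtype), logits.requires_grad, (logits,))

    def _bwd(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(g * grad / n)
    out._backward = _bwd
    return out


def _im2col(xp: np.ndarray, k: int, stride: int):
    # xp: (B, C, Hp, Wp) already padded -> (B, C, Ho, Wo, k, k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution (cross-correlation), NCHW layout.

    ``weight`` has shape (C_out, C_in/groups, k, k); ``groups == C_in`` with
    ``C_out == C_in`` gives a depthwise convolution.
    """
    B, C, H, W = x.data.shape
    Cout, Cg, k, _ = weight.data.shape
    if C % groups or Cout % groups or Cg != C // groups:
        raise ValueError(f"incompatible channels C={C} Cout={Cout} groups={groups}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    Hp, Wp = H + 2 * padding, W + 2 * padding
    depthwise = groups == C == Cout
    parents = (x, weight) if bias is None else (x, weight, bias)

    if depthwise:
        # k*k shifted multiply-adds, vectorized over all channels
        Ho = (Hp - k) // stride + 1
        Wo = (Wp - k) // stride + 1
        out_d = np.zeros((B, C, Ho, Wo), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                out_d += weight.data[None, :, 0, i, j, None, None] \
                    * xp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride]
        if bias is not None:
            out_d += bias.data.reshape(1, Cout, 1, 1)
        if _MACS is not None:
            _MACS[0] += B * Cout * Ho * Wo * k * k
        out = Tensor(out_d, any(p.requires_grad for p in parents), parents)

        def _bwd_dw(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            gx = np.zeros((B, C, Hp, Wp), dtype=g.dtype) if x.requires_grad else None
            for i in range(k):
                for j in range(k):
                    sl = (slice(None), slice(None),
                          slice(i, i + stride * Ho, stride),
                          slice(j, j + stride * Wo, stride))
                    if weight.requires_grad:
                        weight._accum_index((slice(None), 0, i, j),
                                            (g * xp[sl]).sum(axis=(0, 2, 3)))
                    if gx is not None:
                        gx[sl] += weight.data[None, :, 0, i, j, None, None] * g
            if gx is not None:
                x._accum(gx[:, :, padding:Hp - padding, padding:Wp - padding]
                         if padding else gx)
        out._backward = _bwd_dw
        return out

    cols = _im2col(xp, k, stride)                      # (B, C, Ho, Wo, k, k)
    Ho, Wo = cols.shape[2], cols.shape[3]
    cols_g = cols.reshape(B, groups, C // groups, Ho, Wo, k, k)
    w_g = weight.data.reshape(groups, Cout // groups, Cg, k, k)
    out_d = np.einsum("bgchwij,gocij->bgohw", cols_g, w_g, optimize=True)
    out_d = out_d.reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out_d = out_d + bias.data.reshape(1, Cout, 1, 1)
    if _MACS is not None:
        _MACS[0] += B * Cout * Ho * Wo * (C // groups) * k * k
    out = Tensor(out_d, any(p.requires_grad for p in parents), parents)

    def _bwd(g):
        g_g = g.reshape(B, groups, Cout // groups, Ho, Wo)
        if weight.requires_grad:
            gw = np.einsum("bgohw,bgchwij->gocij", g_g, cols_g, optimize=True)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("bgohw,gocij->bgchwij", g_g, w_g, optimize=True)
            gcols = gcols.reshape(B, C, Ho, Wo, k, k)
            gx = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
            for i in range(k):
                for j in range(k):
                    gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] \
                        += gcols[:, :, :, :, i, j]
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)
    out._backward = _bwd
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int | None = None,
              padding: int = 0) -> Tensor:
    stride = stride or kernel
    B, C, H, W = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    win = _im2col(xp, kernel, stride)                  # (B, C, Ho, Wo, k, k)
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(flat.max(axis=-1), x.requires_grad, (x,))

    def _bwd(g):
        gx = np.zeros((B, C, H + 2 * padding, W + 2 * padding), dtype=g.dtype)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        for i in range(kernel):
            for j in range(kernel):  # stride-grid slices are disjoint per (i,j)
                gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] \
                    += g * ((ki == i) & (kj == j))
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accum(gx)
    out._backward = _bwd
    return out
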