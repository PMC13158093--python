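"""Minimal reverse-mode autodiff on numpy arrays, with the layers the
3D C-Vit network needs: 3D (grouped/depthwise) convolution, linear maps,
layer normalisation, softmax attention, GELU, dropout, and a BCE-with-logits
loss, plus an Adam optimiser.

Design notes
------------
* A :class:`Tensor` wraps a numpy array and records a closure that
  accumulates gradients into its parents; ``backward`` runs a topological
  sweep.  Broadcasting in elementwise ops is undone on the way back by
  summing over broadcast axes.
* Heavy primitives (conv3d, layernorm, softmax, bce) are fused: their
  backward passes are hand-written rather than composed, for speed and
  memory.  Every fused backward is checked against central finite
  differences in the test suite.
* Everything is deterministic: the only randomness (init, dropout,
  shuffling) flows through explicitly passed ``numpy.random.Generator``s.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv3d",
    "LayerNorm",
    "Adam",
    "concat",
    "gelu",
    "relu",
    "sigmoid",
    "softmax",
    "dropout",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the autodiff bookkeeping to backprop through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}{tag})"

    def _needs_graph(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype if
                                      np.issubdtype(self.data.dtype, np.floating) is False
                                      else self.data.dtype)
        self.grad = self.grad + grad

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad or a._backward:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad or b._backward:
                b._accumulate(_unbroadcast(g, b.data.shape))

        if self._needs_graph(other) or self._backward or other._backward:
            return Tensor(out_data, True, (self, other), bwd)
        return Tensor(out_data)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accumulate(-g)
        if self.requires_grad or self._backward:
            return Tensor(-self.data, True, (self,), bwd)
        return Tensor(-self.data)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad or a._backward:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad or b._backward:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        if self._needs_graph(other) or self._backward or other._backward:
            return Tensor(out_data, True, (self, other), bwd)
        return Tensor(out_data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad or a._backward:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad or b._backward:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        if self._needs_graph(other) or self._backward or other._backward:
            return Tensor(out_data, True, (self, other), bwd)
        return Tensor(out_data)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g, a=self, b=other):
            if a.requires_grad or a._backward:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad or b._backward:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        if self._needs_graph(other) or self._backward or other._backward:
            return Tensor(out_data, True, (self, other), bwd)
        return Tensor(out_data)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bwd(g, a=self):
            a._accumulate(g.reshape(a.data.shape))

        if self.requires_grad or self._backward:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bwd(g, a=self, inv=tuple(inv)):
            a._accumulate(g.transpose(inv))

        if self.requires_grad or self._backward:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        if self.requires_grad or self._backward:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        if self.requires_grad or self._backward:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, y=out_data):
            a._accumulate(g * y)

        if self.requires_grad or self._backward:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g, a=self):
            a._accumulate(g / a.data)

        if self.requires_grad or self._backward:
            return Tensor(out_data, True, (self,), bwd)
        return Tensor(out_data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data


def Parameter(data) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# fused functional primitives
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def bwd(g, a=x, m=(x.data > 0)):
        a._accumulate(g * m)

    if x.requires_grad or x._backward:
        return Tensor(out_data, True, (x,), bwd)
    return Tensor(out_data)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g, a=x, y=out_data):
        a._accumulate(g * y * (1.0 - y))

    if x.requires_grad or x._backward:
        return Tensor(out_data, True, (x,), bwd)
    return Tensor(out_data)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) GELU."""
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out_data = x.data * phi

    def bwd(g, a=x, phi=phi):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data ** 2)
        a._accumulate(g * (phi + a.data * pdf))

    if x.requires_grad or x._backward:
        return Tensor(out_data, True, (x,), bwd)
    return Tensor(out_data)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis``; raises on NaN input rather than emitting NaN."""
    if np.isnan(x.data).any():
        raise FloatingPointError("NaN entered softmax")
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g, a=x, y=y, axis=axis):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    if x.requires_grad or x._backward:
        return Tensor(y, True, (x,), bwd)
    return Tensor(y)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, ts=tensors, splits=splits, axis=axis):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._backward:
                t._accumulate(piece)

    if any(t.requires_grad or t._backward for t in tensors):
        return Tensor(out_data, True, tuple(tensors), bwd)
    return Tensor(out_data)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def bwd(g, a=x, gm=gamma, bt=beta, xhat=xhat, inv=inv):
        n = a.data.shape[-1]
        if gm.requires_grad:
            gm._accumulate(_unbroadcast(g * xhat, gm.data.shape))
        if bt.requires_grad:
            bt._accumulate(_unbroadcast(g, bt.data.shape))
        if a.requires_grad or a._backward:
            gx = g * gm.data
            t1 = gx - gx.mean(axis=-1, keepdims=True)
            t2 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(inv * (t1 - t2))

    if x._needs_graph(gamma, beta) or x._backward:
        return Tensor(out_data, True, (x, gamma, beta), bwd)
    return Tensor(out_data)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(keep)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype).reshape(z.shape)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = np.array(loss.mean(), dtype=z.dtype)

    def bwd(g, a=logits, y=y):
        p = 1.0 / (1.0 + np.exp(-a.data))
        a._accumulate(g * (p - y) / a.data.size)

    if logits.requires_grad or logits._backward:
        return Tensor(out_data, True, (logits,), bwd)
    return Tensor(out_data)


# ---------------------------------------------------------------------------
# 3D convolution
# ---------------------------------------------------------------------------

def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError("expected a length-3 tuple")
        return tuple(int(i) for i in v)
    return (int(v),) * 3


def _conv3d_cols(xd: np.ndarray, ksize, stride, padding):
    k1, k2, k3 = ksize
    s1, s2, s3 = stride
    p1, p2, p3 = padding
    xp = np.pad(xd, ((0, 0), (0, 0), (p1, p1), (p2, p2), (p3, p3)))
    win = sliding_window_view(xp, (k1, k2, k3), axis=(2, 3, 4))
    win = win[:, :, ::s1, ::s2, ::s3]
    return xp.shape, win  # win: [B, C, Do, Ho, Wo, k1, k2, k3] (a view)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0,
           groups: int = 1) -> Tensor:
    """Grouped 3D convolution (cross-correlation), NCDHW layout.

    ``w`` has shape [C_out, C_in/groups, k1, k2, k3]; depthwise convolution is
    ``groups == C_in`` with one filter per channel.
    """
    stride = _triple(stride)
    padding = _triple(padding)
    B, Cin, D, H, W = x.shape
    Cout, Cin_g, k1, k2, k3 = w.shape
    if Cin % groups or Cout % groups:
        raise ValueError(f"channels ({Cin}->{Cout}) not divisible by groups={groups}")
    if Cin_g != Cin // groups:
        raise ValueError("weight shape inconsistent with groups")
    for name, ext, k, p, s in zip("DHW", (D, H, W), (k1, k2, k3), padding, stride):
        out_ext = (ext + 2 * p - k) // s + 1
        if out_ext <= 0:
            raise ValueError(
                f"non-positive output extent on axis {name}: "
                f"(in={ext}, K={k}, P={p}, S={s}) -> {out_ext}")
    _, win = _conv3d_cols(x.data, (k1, k2, k3), stride, padding)
    Do, Ho, Wo = win.shape[2:5]
    V = Do * Ho * Wo
    K = k1 * k2 * k3
    g = groups
    # [B, g, Cin_g, V, K] -> [B, g, V, Cin_g*K]
    cols = win.reshape(B, g, Cin_g, V, K).transpose(0, 1, 3, 2, 4).reshape(B, g, V, Cin_g * K)
    wg = w.data.reshape(g, Cout // g, Cin_g * K)
    out = np.einsum("gok,bgvk->bgov", wg, cols, optimize=True)
    out = out.reshape(B, Cout, Do, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(gout, a=x, w_=w, b_=b):
        go = gout.reshape(B, g, Cout // g, V)
        if w_.requires_grad:
            _, win2 = _conv3d_cols(a.data, (k1, k2, k3), stride, padding)
            cols2 = win2.reshape(B, g, Cin_g, V, K).transpose(0, 1, 3, 2, 4)
            cols2 = cols2.reshape(B, g, V, Cin_g * K)
            gw = np.einsum("bgov,bgvk->gok", go, cols2, optimize=True)
            w_._accumulate(gw.reshape(w_.data.shape))
        if b_ is not None and b_.requires_grad:
            b_._accumulate(gout.sum(axis=(0, 2, 3, 4)).reshape(b_.data.shape))
        if a.requires_grad or a._backward:
            gcols = np.einsum("gok,bgov->bgvk", wg, go, optimize=True)
            gcols = gcols.reshape(B, g, V, Cin_g, K).transpose(0, 1, 3, 2, 4)
            gcols = gcols.reshape(B, Cin, Do, Ho, Wo, k1, k2, k3)
            p1, p2, p3 = padding
            s1, s2, s3 = stride
            gx = np.zeros((B, Cin, D + 2 * p1, H + 2 * p2, W + 2 * p3),
                          dtype=a.data.dtype)
            for i in range(k1):
                for j in range(k2):
                    for l in range(k3):
                        gx[:, :, i:i + s1 * Do:s1, j:j + s2 * Ho:s2,
                           l:l + s3 * Wo:s3] += gcols[..., i, j, l]
            gx = gx[:, :, p1:p1 + D, p2:p2 + H, p3:p3 + W]
            a._accumulate(gx)

    if any(p.requires_grad or p._backward for p in parents):
        return Tensor(out, True, parents, bwd)
    return Tensor(out)


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Module:
    """Parameter container; subclasses set Tensor/Module/list attributes."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            out.extend(_collect(v))
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for k, v in vars(self).items():
            out.extend(_collect_named(v, f"{prefix}{k}"))
        return out

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        missing = set(named) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch: {sorted(missing)}")
        for k, p in named.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_named(v, name: str) -> list[tuple[str, Tensor]]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [(name, v)]
    if isinstance(v, Module):
        return v.named_parameters(prefix=name + ".")
    if isinstance(v, (list, tuple)):
        out = []
        for i, item in enumerate(v):
            out.extend(_collect_named(item, f"{name}.{i}"))
        return out
    return []


class Linear(Module):
    """Affine map on the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init: str = "trunc_normal", std: float = 0.02,
                 dtype=np.float64):
        if init == "trunc_normal":
            w = _trunc_normal(rng, (d_in, d_out), std)
        elif init == "kaiming":
            w = rng.standard_normal((d_in, d_out)) * math.sqrt(2.0 / d_in)
        else:
            raise ValueError(init)
        self.w = Parameter(w.astype(dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv3d(Module):
    """Grouped 3D convolution layer with Kaiming-normal init."""

    def __init__(self, c_in: int, c_out: int, kernel=3, stride=1, padding=1,
                 groups: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.groups = groups
        fan_in = (c_in // groups) * int(np.prod(kernel))
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((c_out, c_in // groups, *kernel)) * math.sqrt(2.0 / fan_in)
        self.w = Parameter(w.astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, self.stride, self.padding, self.groups)


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float64):
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


def _trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) resampled into [-2 std, 2 std]."""
    out = rng.standard_normal(shape) * std
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum())) * std
        bad = np.abs(out) > 2 * std
    return out


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, no weight decay)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
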