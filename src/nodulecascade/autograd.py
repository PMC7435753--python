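"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the primitives the cascaded detection networks need:
dense broadcasting arithmetic, 2D (dilated, strided) convolution and
transposed convolution, pooling/resampling, batch normalisation and the
usual pointwise nonlinearities, plus a small ``Module``/``Parameter``
layer system and an Adam optimizer.

All tensors are ``float32`` and laid out ``(N, C, H, W)`` for images.
Convolutions are evaluated tap-by-tap (one strided slice + matmul per
kernel element), which is memory-light and fast enough for the desk-scale
networks this package trains on CPU.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Adam",
    "concat",
    "relu",
    "sigmoid",
    "avg_pool2d",
    "max_pool2x2",
    "upsample_nearest",
    "conv2d",
    "conv_transpose2d",
]


def _as_pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        a, b = v
        return int(a), int(b)
    return int(v), int(v)


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source operand."""
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
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # own the buffer: copy views/foreign dtypes, adopt fresh arrays
            if g.dtype != np.float32:
                g = g.astype(np.float32)
            elif g.base is not None:
                g = g.copy()
            self.grad = g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = _node(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _sum_to_shape(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    # -- reductions & shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def abs(self):
        out = _node(np.abs(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        out._backward = bw
        return out

    def sqrt(self):
        sd = np.sqrt(self.data)
        out = _node(sd, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(sd, 1e-12))

        out._backward = bw
        return out


def _wrap(v) -> Tensor:
    return v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float32))


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if isinstance(p, Tensor))
    out._parents = live
    out.requires_grad = any(p.requires_grad for p in live)
    return out


# -- pointwise nonlinearities ---------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = expit(x.data).astype(np.float32)
    out = _node(s, (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bw
    return out


# -- structural ops --------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def avg_pool2d(x: Tensor, factor) -> Tensor:
    """Non-overlapping average pooling by an integer factor per axis."""
    fh, fw = _as_pair(factor)
    n, c, h, w = x.data.shape
    if h % fh or w % fw:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool factor ({fh},{fw})")
    xr = x.data.reshape(n, c, h // fh, fh, w // fw, fw)
    out = _node(xr.mean(axis=(3, 5)), (x,))

    def bw(g):
        if x.requires_grad:
            g4 = np.repeat(np.repeat(g, fh, axis=2), fw, axis=3) / (fh * fw)
            x._accum(g4)

    out._backward = bw
    return out


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2x2 needs even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    m = xr.max(axis=(3, 5))
    out = _node(m, (x,))
    mask = (xr == m[:, :, :, None, :, None]).astype(np.float32)

    def bw(g):
        if x.requires_grad:
            gx = mask * g[:, :, :, None, :, None]
            x._accum(gx.reshape(n, c, h, w))

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor) -> Tensor:
    fh, fw = _as_pair(factor)
    out = _node(np.repeat(np.repeat(x.data, fh, axis=2), fw, axis=3), (x,))

    def bw(g):
        if x.requires_grad:
            n, c, h, w = x.data.shape
            gr = g.reshape(n, c, h, fh, w, fw).sum(axis=(3, 5))
            x._accum(gr)

    out._backward = bw
    return out


# -- convolutions -----------------------------------------------------------

def _im2col(xp: np.ndarray, kh, kw, sh, sw, dh, dw, oh, ow) -> np.ndarray:
    """Gather kernel taps into a (C*kh*kw, N*oh*ow) matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((c, kh, kw, n, oh, ow), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki * dh : ki * dh + (oh - 1) * sh + 1 : sh,
                    kj * dw : kj * dw + (ow - 1) * sw + 1 : sw]
            cols[:, ki, kj] = xs.transpose(1, 0, 2, 3)
    return cols.reshape(c * kh * kw, n * oh * ow)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0, dilation=1) -> Tensor:
    """2D cross-correlation; ``w`` has shape (out_ch, in_ch, kh, kw)."""
    sh, sw = _as_pair(stride)
    ph, pw = _as_pair(padding)
    dh, dw = _as_pair(dilation)
    n, c, h, wd = x.data.shape
    oc, ic, kh, kw = w.data.shape
    if ic != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {ic}")
    nh = kh + (kh - 1) * (dh - 1)
    nw = kw + (kw - 1) * (dw - 1)
    oh = (h + 2 * ph - nh) // sh + 1
    ow = (wd + 2 * pw - nw) // sw + 1
    if oh < 1 or ow < 1:
        raise ValueError("effective kernel exceeds padded input")
    def padded():
        if ph or pw:
            return np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        return x.data

    cols = _im2col(padded(), kh, kw, sh, sw, dh, dw, oh, ow)
    w2 = w.data.reshape(oc, c * kh * kw)
    out_data = np.ascontiguousarray(
        (w2 @ cols).reshape(oc, n, oh, ow).transpose(1, 0, 2, 3))
    del cols  # rebuilt in the backward pass; keeping it would inflate activation memory
    if b is not None:
        out_data += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        g2 = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(oc, n * oh * ow)
        if w.requires_grad:
            cols = _im2col(padded(), kh, kw, sh, sw, dh, dw, oh, ow)
            w._accum((g2 @ cols.T).reshape(w.data.shape))
            del cols
        if x.requires_grad:
            gcols = (w2.T @ g2).reshape(c, kh, kw, n, oh, ow)
            tgt = np.zeros((n, c, h + 2 * ph, wd + 2 * pw), dtype=np.float32)
            for ki in range(kh):
                for kj in range(kw):
                    tgt[:, :, ki * dh : ki * dh + (oh - 1) * sh + 1 : sh,
                        kj * dw : kj * dw + (ow - 1) * sw + 1 : sw] += \
                        gcols[:, ki, kj].transpose(1, 0, 2, 3)
            x._accum(tgt[:, :, ph : ph + h, pw : pw + wd] if (ph or pw)
                     else tgt)

    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0,
                     output_padding=0, dilation=1) -> Tensor:
    """Transposed 2D convolution; ``w`` has shape (in_ch, out_ch, kh, kw)."""
    sh, sw = _as_pair(stride)
    ph, pw = _as_pair(padding)
    oph, opw = _as_pair(output_padding)
    dh, dw = _as_pair(dilation)
    n, c, h, wd = x.data.shape
    ic, oc, kh, kw = w.data.shape
    if ic != c:
        raise ValueError(f"conv_transpose2d channel mismatch: input has {c}, weight expects {ic}")
    nh = kh + (kh - 1) * (dh - 1)
    nw = kw + (kw - 1) * (dw - 1)
    hb = (h - 1) * sh + nh + oph
    wb = (wd - 1) * sw + nw + opw
    oh = hb - 2 * ph
    ow = wb - 2 * pw
    if oh < 1 or ow < 1:
        raise ValueError("padding exceeds transposed-convolution extent")
    x2 = np.ascontiguousarray(x.data.transpose(1, 0, 2, 3)).reshape(c, n * h * wd)
    w2 = w.data.reshape(c, oc * kh * kw)
    prod = (w2.T @ x2).reshape(oc, kh, kw, n, h, wd)
    buf = np.zeros((n, oc, hb, wb), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            buf[:, :, ki * dh : ki * dh + (h - 1) * sh + 1 : sh,
                kj * dw : kj * dw + (wd - 1) * sw + 1 : sw] += \
                prod[:, ki, kj].transpose(1, 0, 2, 3)
    out_data = buf[:, :, ph : ph + oh, pw : pw + ow]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(np.ascontiguousarray(out_data), parents)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gbuf = np.zeros((n, oc, hb, wb), dtype=np.float32)
        gbuf[:, :, ph : ph + oh, pw : pw + ow] = g
        gcols = _im2col(gbuf, kh, kw, sh, sw, dh, dw, h, wd)  # (oc*kh*kw, n*h*wd)
        if w.requires_grad:
            w._accum((x2 @ gcols.T).reshape(w.data.shape))
        if x.requires_grad:
            gx2 = w2 @ gcols  # (c, n*h*wd)
            x._accum(np.ascontiguousarray(
                gx2.reshape(c, n, h, wd).transpose(1, 0, 2, 3)))

    out._backward = bw
    return out


# -- modules ----------------------------------------------------------------

class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for v in self.__dict__.values():
            self._collect_value(v, params, seen)

    @staticmethod
    def _collect_value(v, params, seen):
        if isinstance(v, Parameter):
            if id(v) not in seen:
                seen.add(id(v))
                params.append(v)
        elif isinstance(v, Module):
            v._collect(params, seen)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._collect_value(item, params, seen)

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            self._set_mode(v, mode)
        return self

    @staticmethod
    def _set_mode(v, mode):
        if isinstance(v, Module):
            v.train(mode)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._set_mode(item, mode)

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        self._state("", state)
        return state

    def _state(self, prefix: str, state: dict) -> None:
        for k, v in self.__dict__.items():
            self._state_value(f"{prefix}{k}", v, state)

    @classmethod
    def _state_value(cls, key, v, state):
        if isinstance(v, Parameter):
            state[key] = v.data
        elif isinstance(v, np.ndarray):
            state[key] = v
        elif isinstance(v, Module):
            v._state(key + ".", state)
        elif isinstance(v, (list, tuple)):
            for i, item in enumerate(v):
                cls._state_value(f"{key}.{i}", item, state)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in checkpoint: {sorted(missing)[:5]}...")
        self._load("", state)

    def _load(self, prefix: str, state: dict) -> None:
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Parameter):
                v.data = np.asarray(state[key], dtype=np.float32).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                setattr(self, k, np.asarray(state[key], dtype=np.float32).reshape(v.shape))
            elif isinstance(v, Module):
                v._load(key + ".", state)
            elif isinstance(v, (list, tuple)):
                self._load_seq(key, v, state)

    @classmethod
    def _load_seq(cls, key, seq, state):
        for i, item in enumerate(seq):
            if isinstance(item, Parameter):
                item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float32).reshape(item.data.shape)
            elif isinstance(item, Module):
                item._load(f"{key}.{i}.", state)
            elif isinstance(item, (list, tuple)):
                cls._load_seq(f"{key}.{i}", item, state)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, padding=0,
                 dilation=1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel counts must be >= 1")
        kh, kw = _as_pair(kernel)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, padding=0,
                 output_padding=0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = _as_pair(kernel)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, kh, kw), in_ch * kh * kw))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride,
                                self.padding, self.output_padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        # fused normalisation: a single graph node with a closed-form
        # backward keeps both runtime and activation memory low
        batch_stats = self.training
        if batch_stats:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x.data - mu[None, :, None, None].astype(np.float32)) * ivar[None, :, None, None]
        gamma, beta = self.gamma, self.beta
        out = _node(xhat * gamma.data[None, :, None, None]
                    + beta.data[None, :, None, None], (x, gamma, beta))

        def bw(g):
            gsum = g.sum(axis=(0, 2, 3))
            gxhat_sum = (g * xhat).sum(axis=(0, 2, 3))
            if beta.requires_grad:
                beta._accum(gsum)
            if gamma.requires_grad:
                gamma._accum(gxhat_sum)
            if x.requires_grad:
                scale = (gamma.data * ivar)[None, :, None, None]
                if batch_stats:
                    m = g.shape[0] * g.shape[2] * g.shape[3]
                    dx = scale * (g - gsum[None, :, None, None] / m
                                  - xhat * (gxhat_sum[None, :, None, None] / m))
                else:
                    dx = scale * g
                x._accum(dx)

        out._backward = bw
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return sigmoid(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
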