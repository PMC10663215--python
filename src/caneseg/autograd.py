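"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical engine behind the segmentation network: a ``Tensor``
wrapping a float32 ndarray, a small set of differentiable operations
(elementwise arithmetic, reductions, 2-D convolution, batch normalization,
bilinear interpolation, concatenation), ``Module``/``Sequential`` containers
and an Adam optimizer.  Convolutions are evaluated as a loop over kernel
taps, each tap a single BLAS tensor contraction, which is both memory-lean
and fast for the small kernels (1x1, 3x3, 3x1, 1x3) used here.

Gradients flow through a topologically sorted tape built on the fly; only
tensors created with ``requires_grad=True`` (parameters) and their
descendants participate.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "ReLU6",
    "Sigmoid",
    "Adam",
    "relu",
    "relu6",
    "sigmoid",
    "log_softmax",
    "softmax",
    "upsample_bilinear",
    "concat",
    "no_grad",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _sum_to_shape(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- tape plumbing ----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        else:
            out.requires_grad = False
            out._parents = ()
            out._backward = None
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs here are deep (100+ layers)
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free the closure as soon as it has run
        # tape is consumed; drop references so intermediate buffers free up
        for node in topo:
            node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True) if g.base is not None else g.astype(np.float32, copy=False)
        else:
            self.grad = self.grad + g

    # -- basics -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_sum_to_shape(g, a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to_shape(g, b.data.shape))

        return Tensor._make(self.data + other.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-self.data, (a,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_sum_to_shape(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to_shape(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_sum_to_shape(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_sum_to_shape(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(self.data / other.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = self.data ** exponent

        def backward(g):
            a._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(self.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (a,), backward)

    def clip(self, lo: float | None, hi: float | None):
        """Clamp values; gradient passes only where the input was in range."""
        a = self
        out_data = np.clip(self.data, lo, hi)
        src = self.data

        def backward(g):
            inside = None
            if lo is not None:
                inside = src >= lo
            if hi is not None:
                upper = src <= hi
                inside = upper if inside is None else (inside & upper)
            a._accum(g if inside is None else g * inside)

        return Tensor._make(out_data, (a,), backward)

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape))

        return Tensor._make(np.asarray(out_data, dtype=np.float32), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        old = self.data.shape

        def backward(g):
            a._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (a,), backward)

    def transpose(self, axes: Sequence[int]):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full)

        return Tensor._make(self.data[idx], (a,), backward)


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    return x.clip(0.0, None)


def relu6(x: Tensor) -> Tensor:
    return x.clip(0.0, 6.0)


def sigmoid(x: Tensor) -> Tensor:
    a = x
    # stable: exp of a non-positive argument on both branches
    z = np.exp(-np.abs(x.data))
    out_data = np.where(x.data >= 0, 1.0 / (1.0 + z), z / (1.0 + z))

    def backward(g):
        a._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data.astype(np.float32), (a,), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    a = x
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    ez = np.exp(z)
    sez = ez.sum(axis=axis, keepdims=True)
    out_data = z - np.log(sez)

    def backward(g):
        # d/dx log_softmax = g - softmax * sum(g)
        sm = ez / sez
        a._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data.astype(np.float32), (a,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    parts = list(tensors)
    sizes = [t.data.shape[axis] for t in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in parts], axis=axis), tuple(parts), backward
    )


# ---------------------------------------------------------------------------
# bilinear interpolation (as separable interpolation matrices)
# ---------------------------------------------------------------------------

def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense (n_out, n_in) bilinear interpolation matrix, half-pixel centers."""
    A = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1)
        lo = int(math.floor(src))
        hi = min(lo + 1, n_in - 1)
        w = src - lo
        A[o, lo] += 1.0 - w
        A[o, hi] += w
    return A


_interp_cache: dict[tuple[int, int], np.ndarray] = {}


def _interp(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _interp_cache:
        _interp_cache[key] = _interp_matrix(n_out, n_in)
    return _interp_cache[key]


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resize an NCHW tensor spatially with bilinear interpolation."""
    a = x
    N, C, H, W = x.data.shape
    Ho, Wo = size
    A = _interp(Ho, H)  # (Ho, H)
    B = _interp(Wo, W)  # (Wo, W)
    out_data = np.einsum("oh,nchw,pw->ncop", A, x.data, B, optimize=True)

    def backward(g):
        a._accum(np.einsum("oh,ncop,pw->nchw", A, g, B, optimize=True))

    return Tensor._make(out_data.astype(np.float32), (a,), backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, call syntax."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []

        def visit(mod: Module, prefix: str):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out.append((f"{prefix}{k}", v))
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")

        visit(self, "")
        return out

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        # running statistics are state but not parameters
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bnstat{i}.mean"] = m.running_mean.copy()
                state[f"__bnstat{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bnstat{i}.mean"], dtype=np.float32)
                m.running_var = np.asarray(state[f"__bnstat{i}.var"], dtype=np.float32)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class ReLU6(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu6(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return sigmoid(x)


class Conv2d(Module):
    """2-D convolution, optionally depthwise (groups == in_channels).

    Weight layout ``(out, in/groups, kh, kw)``; Kaiming-normal fan-out
    initialization.  Evaluation loops over the kh*kw kernel taps; each tap is
    one tensordot (standard conv) or one broadcast multiply (depthwise).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int | tuple[int, int],
        stride: int = 1,
        padding: int | tuple[int, int] | None = None,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if groups not in (1, in_channels):
            raise ValueError("only groups == 1 or depthwise (groups == in_channels) supported")
        if groups == in_channels and out_channels != in_channels:
            raise ValueError("depthwise convolution requires out_channels == in_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = (kh, kw)
        self.stride = stride
        if padding is None:  # 'same' padding for stride 1, standard half padding otherwise
            padding = (dilation * (kh - 1) // 2, dilation * (kw - 1) // 2)
        self.padding = (padding, padding) if isinstance(padding, int) else padding
        self.dilation = dilation
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_out = out_channels * kh * kw // groups
        std = math.sqrt(2.0 / fan_out)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_channels, in_channels // groups, kh, kw)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        ph, pw = self.padding
        eh = self.dilation * (kh - 1) + 1
        ew = self.dilation * (kw - 1) + 1
        return (h + 2 * ph - eh) // self.stride + 1, (w + 2 * pw - ew) // self.stride + 1

    def flops(self, h: int, w: int) -> int:
        ho, wo = self.out_size(h, w)
        kh, kw = self.kernel
        macs = ho * wo * self.out_channels * (self.in_channels // self.groups) * kh * kw
        fl = 2 * macs
        if self.bias is not None:
            fl += ho * wo * self.out_channels
        return fl

    def forward(self, x: Tensor) -> Tensor:
        a, wt = x, self.weight
        N, C, H, W = x.data.shape
        kh, kw = self.kernel
        ph, pw = self.padding
        s, d = self.stride, self.dilation
        Ho, Wo = self.out_size(H, W)
        if ph or pw:
            xp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=np.float32)
            xp[:, :, ph : ph + H, pw : pw + W] = x.data
        else:
            xp = x.data
        w_np = wt.data
        depthwise = self.groups == C and C > 1
        if depthwise:
            out = np.zeros((N, self.out_channels, Ho, Wo), dtype=np.float32)
            taps = [(i, j) for i in range(kh) for j in range(kw)]
            for i, j in taps:
                xs = xp[:, :, i * d : i * d + (Ho - 1) * s + 1 : s,
                         j * d : j * d + (Wo - 1) * s + 1 : s]
                out += w_np[:, 0, i, j][None, :, None, None] * xs
            cols = None
        else:
            # im2col + one BLAS matmul; for 1x1 stride-1 this is a pure view
            if kh == kw == 1 and s == 1:
                cols = xp.reshape(N, C, Ho * Wo)
            else:
                eh = d * (kh - 1) + 1
                ew = d * (kw - 1) + 1
                swv = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
                # (N, C, Ho, Wo, kh, kw) strided view, then pack to matmul layout
                view = swv[:, :, ::s, ::s, ::d, ::d]
                cols = np.ascontiguousarray(view.transpose(0, 1, 4, 5, 2, 3)).reshape(
                    N, C * kh * kw, Ho * Wo
                )
            w2 = w_np.reshape(self.out_channels, C * kh * kw)
            out = np.matmul(w2, cols).reshape(N, self.out_channels, Ho, Wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        pads = (ph, pw)
        xp_kept = xp  # kept alive for the weight/input gradients

        def backward(g):
            gxp = np.zeros_like(xp_kept) if a.requires_grad else None
            if depthwise:
                gw = np.zeros_like(w_np) if wt.requires_grad else None
                for i, j in taps:
                    hsl = slice(i * d, i * d + (Ho - 1) * s + 1, s)
                    wsl = slice(j * d, j * d + (Wo - 1) * s + 1, s)
                    if gw is not None:
                        gw[:, 0, i, j] = (g * xp_kept[:, :, hsl, wsl]).sum(axis=(0, 2, 3))
                    if gxp is not None:
                        gxp[:, :, hsl, wsl] += w_np[:, 0, i, j][None, :, None, None] * g
                if gw is not None:
                    wt._accum(gw)
            else:
                g2 = g.reshape(N, self.out_channels, Ho * Wo)
                if wt.requires_grad:
                    gw2 = np.tensordot(g2, cols, axes=([0, 2], [0, 2]))
                    wt._accum(gw2.reshape(w_np.shape))
                if gxp is not None:
                    w2 = w_np.reshape(self.out_channels, C * kh * kw)
                    gcols = np.matmul(w2.T, g2)  # (N, C*kh*kw, Ho*Wo)
                    if kh == kw == 1 and s == 1:
                        gxp += gcols.reshape(gxp.shape)
                    else:
                        gc = gcols.reshape(N, C, kh, kw, Ho, Wo)
                        for i in range(kh):
                            for j in range(kw):
                                gxp[:, :, i * d : i * d + (Ho - 1) * s + 1 : s,
                                    j * d : j * d + (Wo - 1) * s + 1 : s] += gc[:, :, i, j]
            if gxp is not None:
                hs = slice(pads[0], gxp.shape[2] - pads[0]) if pads[0] else slice(None)
                ws = slice(pads[1], gxp.shape[3] - pads[1]) if pads[1] else slice(None)
                a._accum(gxp[:, :, hs, ws])
            if self.bias is not None and self.bias.requires_grad:
                self.bias._accum(g.sum(axis=(0, 2, 3)))

        parents = (a, wt) if self.bias is None else (a, wt, self.bias)
        return Tensor._make(out, parents, backward)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def flops(self, h: int, w: int) -> int:
        return 2 * self.num_features * h * w

    def forward(self, x: Tensor) -> Tensor:
        a, gamma, beta = x, self.weight, self.bias
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3), dtype=np.float64)
            var = (x.data.astype(np.float64) ** 2).mean(axis=(0, 2, 3)) - mean**2
            var = np.maximum(var, 0.0)
            mean = mean.astype(np.float32)
            var = var.astype(np.float32)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        scale = (gamma.data * inv)[None, :, None, None]
        shift = (beta.data - gamma.data * inv * mean)[None, :, None, None]
        out = x.data * scale + shift
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        training = self.training
        src = x.data

        def backward(g):
            xhat = (src - mean[None, :, None, None]) * inv[None, :, None, None]
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                gi = g * gamma.data[None, :, None, None]
                if training:
                    # full batch-norm backward through the batch statistics
                    t1 = gi.sum(axis=(0, 2, 3), keepdims=True)
                    t2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    dx = (gi - t1 / m - xhat * t2 / m) * inv[None, :, None, None]
                else:
                    dx = gi * inv[None, :, None, None]
                a._accum(dx.astype(np.float32))

        return Tensor._make(out.astype(np.float32), (a, gamma, beta), backward)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
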