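"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical engine behind every neural component in the package:
a tape-based :class:`Tensor` with the operator set a convolutional
encoder-decoder captioner needs (dense/grouped convolution, attention
primitives, layer normalisation, embeddings), a small :class:`Module`
hierarchy, and an Adam optimiser with per-group learning rates.

Gradients flow through a dynamically built DAG; ``Tensor.backward`` runs a
topological sweep accumulating ``.grad`` on every tensor that requires it.
Broadcasting follows numpy semantics; the backward pass sums gradients back
to the operand shapes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Adam",
    "tensor",
    "concatenate",
    "stack",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autodiff core --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def _track(self, parents: Sequence["Tensor"], backward) -> "Tensor":
        needs = any(p.requires_grad or p._parents for p in parents)
        if needs:
            self._parents = tuple(parents)
            self._backward = backward
            self.requires_grad = self.requires_grad or False
        return self

    @staticmethod
    def _needs(parents: Sequence["Tensor"]) -> bool:
        return any(p.requires_grad or p._parents for p in parents)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data)
        return out._track(
            (self, other),
            lambda g: (
                _sum_to_shape(g, self.shape),
                _sum_to_shape(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data)
        return out._track((self,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data)
        return out._track(
            (self, other),
            lambda g: (
                _sum_to_shape(g * other.data, self.shape),
                _sum_to_shape(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data / other.data)
        return out._track(
            (self, other),
            lambda g: (
                _sum_to_shape(g / other.data, self.shape),
                _sum_to_shape(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p)
        return out._track((self,), lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data)

        def back(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else g * b
            else:
                gb_side = np.swapaxes(b, -1, -2) if b.ndim > 1 else b[None, :]
                ga = g[..., None] @ gb_side[..., None, :] if g.ndim == a.ndim - 1 else g @ gb_side
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ g[..., None]
                gb = gb[..., 0]
            else:
                ga_side = np.swapaxes(a, -1, -2) if a.ndim > 1 else a[:, None]
                gb = ga_side @ (g[..., None, :] if g.ndim == b.ndim - 1 else g)
            return (
                _sum_to_shape(np.asarray(ga), self.shape),
                _sum_to_shape(np.asarray(gb), other.shape),
            )

        return out._track((self, other), back)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0))
        return out._track((self,), lambda g: (g * (self.data > 0),))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s)
        return out._track((self,), lambda g: (g * s * (1.0 - s),))

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t)
        return out._track((self,), lambda g: (g * (1.0 - t * t),))

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e)
        return out._track((self,), lambda g: (g * e,))

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data))
        return out._track((self,), lambda g: (g / self.data,))

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        out = Tensor(r)
        return out._track((self,), lambda g: (g * 0.5 / r,))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return out._track((self,), back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- softmax family --------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s)

        def back(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return out._track((self,), back)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = Tensor(z - lse)
        s = np.exp(z - lse)

        def back(g):
            return (g - s * g.sum(axis=axis, keepdims=True),)

        return out._track((self,), back)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        return out._track((self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))
        return out._track((self,), lambda g: (g.transpose(inv),))

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx])

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return out._track((self,), back)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return out._track(tensors, back)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))

    def back(g):
        return tuple(np.moveaxis(g, axis, 0))

    return out._track(tensors, back)


# -- structured ops ------------------------------------------------------------


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather with scatter-add backward (word embeddings)."""
    ids = np.asarray(ids, dtype=np.int64)
    out = Tensor(table.data[ids])

    def back(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        return (full,)

    return out._track((table,), back)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    oh, ow = cols.shape[4], cols.shape[5]
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    return out[:, :, pad : pad + h, pad : pad + w] if pad else out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (NCHW) via im2col; supports grouped convolution."""
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin_g * groups != cin or cout % groups:
        raise ValueError(
            f"channel mismatch: input {cin} channels, weight expects {cin_g}x{groups} groups of {cout} outputs"
        )
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    # (n, groups, cin_g*kh*kw, oh*ow)
    cols_g = cols.reshape(n, groups, cin_g * kh * kw, oh * ow)
    w_g = weight.data.reshape(groups, cout // groups, cin_g * kh * kw)
    out_data = np.einsum("gok,ngkp->ngop", w_g, cols_g, optimize=True)
    out_data = out_data.reshape(n, cout, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def back(g):
        g_g = g.reshape(n, groups, cout // groups, oh * ow)
        gw = np.einsum("ngop,ngkp->gok", g_g, cols_g, optimize=True).reshape(weight.shape)
        gcols = np.einsum("gok,ngop->ngkp", w_g, g_g, optimize=True)
        gcols = gcols.reshape(n, cin, kh, kw, oh, ow)
        gx = _col2im(gcols, x.shape, kh, kw, stride, padding)
        if bias is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor(out_data)._track(parents, back)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    stride = stride or kernel
    cols, oh, ow = _im2col(x.data, kernel, kernel, stride, 0)
    n, c = x.shape[:2]
    flat = cols.reshape(n, c, kernel * kernel, oh, ow)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def back(g):
        gcols = np.zeros_like(flat)
        np.put_along_axis(gcols, arg[:, :, None], g[:, :, None], axis=2)
        gcols = gcols.reshape(n, c, kernel, kernel, oh, ow)
        return (_col2im(gcols, x.shape, kernel, kernel, stride, 0),)

    return Tensor(out_data)._track((x,), back)


def avg_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    stride = stride or kernel
    cols, oh, ow = _im2col(x.data, kernel, kernel, stride, 0)
    n, c = x.shape[:2]
    flat = cols.reshape(n, c, kernel * kernel, oh, ow)
    out_data = flat.mean(axis=2)

    def back(g):
        gcols = np.broadcast_to(g[:, :, None] / (kernel * kernel), flat.shape).copy()
        gcols = gcols.reshape(n, c, kernel, kernel, oh, ow)
        return (_col2im(gcols, x.shape, kernel, kernel, stride, 0),)

    return Tensor(out_data)._track((x,), back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gamma + beta


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# -- modules -------------------------------------------------------------------


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: tracks parameters and submodules by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for mname, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mname + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Adam:
    """Adam with independent parameter groups (each with its own lr)."""

    def __init__(self, param_groups: Iterable[dict], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.groups = []
        for g in param_groups:
            params = list(g["params"])
            self.groups.append(
                {
                    "params": params,
                    "lr": float(g["lr"]),
                    "m": [np.zeros_like(p.data) for p in params],
                    "v": [np.zeros_like(p.data) for p in params],
                }
            )
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for g in self.groups:
            for i, p in enumerate(g["params"]):
                if p.grad is None:
                    continue
                g["m"][i] = b1 * g["m"][i] + (1 - b1) * p.grad
                g["v"][i] = b2 * g["v"][i] + (1 - b2) * p.grad**2
                mhat = g["m"][i] / bc1
                vhat = g["v"][i] / bc2
                p.data = p.data - g["lr"] * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def scale_lr(self, factor: float) -> None:
        for g in self.groups:
            g["lr"] *= factor

    @property
    def lrs(self) -> list[float]:
        return [g["lr"] for g in self.groups]


def clip_grad_norm(params: Iterable[Parameter], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in params)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad = p.grad * scale
    return total
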