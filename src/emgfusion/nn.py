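"""Minimal reverse-mode autograd and neural-network layers on numpy.

This is the numerical engine behind the dual-branch classifier: a small
tape-based autodiff ``Tensor`` plus the layers the model needs (2-D
convolution via im2col, max pooling, linear maps, a single-layer LSTM,
layer normalisation, dropout, softmax/cross-entropy) and an Adam optimiser
with step-wise learning-rate decay. Everything is CPU numpy; capacity is
kept configurable so the full architecture trains at desk scale.

Gradients are checked against central finite differences in the test
suite; layers take an explicit ``numpy.random.Generator`` for weight
initialisation so training is reproducible from a single seed.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# autograd core

class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in t._backward(g):
                if parent.requires_grad or parent._backward is not None:
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    def zero_grad(self):
        self.grad = None

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other),
                     backward=lambda g: [(self, _unbroadcast(g, self.shape)),
                                         (other, _unbroadcast(g, other.shape))])
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,),
                      backward=lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other),
                     backward=lambda g: [
                         (self, _unbroadcast(g * other.data, self.shape)),
                         (other, _unbroadcast(g * self.data, other.shape))])
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def matmul(self, other: "Tensor") -> "Tensor":
        """2-D or batched 3-D matrix product (no broadcast across batch)."""
        other = self._lift(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bwd(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return [(self, _unbroadcast(ga, a.shape)),
                    (other, _unbroadcast(gb, b.shape))]

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __matmul__ = matmul

    # -- shaping ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), parents=(self,),
                      backward=lambda g: [(self, g.reshape(old))])

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(*axes), parents=(self,),
                      backward=lambda g: [(self, g.transpose(*inv))])

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return [(self, full)]
        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # -- reductions & activations -------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        def bwd(g):
            if axis is None:
                return [(self, np.broadcast_to(g, self.shape).copy())]
            gg = g if keepdims else np.expand_dims(g, axis)
            return [(self, np.broadcast_to(gg, self.shape).copy())]
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,),
                      backward=lambda g: [(self, g * mask)])

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        return Tensor(y, parents=(self,),
                      backward=lambda g: [(self, g * (1 - y * y))])

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor(y, parents=(self,),
                      backward=lambda g: [(self, g * y * (1 - y))])

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return [(self, y * (g - dot))]

        return Tensor(y, parents=(self,), backward=bwd)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return Tensor(np.concatenate(datas, axis=axis),
                  parents=tuple(tensors), backward=bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        return [(t, p.squeeze(axis)) for t, p in zip(tensors, parts)]
    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# fused layers

def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = labels.size
    loss = -logp[np.arange(n), labels].mean()

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return [(logits, g * p / n)]

    return Tensor(loss, parents=(logits,), backward=bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data

    def bwd(g):
        d = x.data.shape[-1]
        dxhat = g * gamma.data
        dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
        dgamma = _unbroadcast(g * xhat, gamma.data.shape)
        dbeta = _unbroadcast(g, beta.data.shape)
        return [(x, dx), (gamma, dgamma), (beta, dbeta)]

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return Tensor(x.data * mask, parents=(x,),
                  backward=lambda g: [(x, g * mask)])


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B, C*kh*kw, Hout*Wout), stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    b, c, ho, wo, _, _ = view.shape
    return (view.transpose(0, 1, 4, 5, 2, 3)
            .reshape(b, c * kh * kw, ho * wo)), (ho, wo)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, pad: int,
            out_hw: tuple) -> np.ndarray:
    """Adjoint of :func:`_im2col` (stride 1)."""
    b, c, h, w = x_shape
    ho, wo = out_hw
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(b, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + ho, j:j + wo] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int = 1) -> Tensor:
    """Same-size 3x3-style convolution, stride 1 (im2col formulation)."""
    B = x.data.shape[0]
    O, C, kh, kw = weight.data.shape
    cols, out_hw = _im2col(x.data, kh, kw, pad)
    wmat = weight.data.reshape(O, -1)
    out = (wmat @ cols) + bias.data.reshape(1, O, 1)
    ho, wo = out_hw
    out_data = out.reshape(B, O, ho, wo)

    def bwd(g):
        gmat = g.reshape(B, O, ho * wo)
        dW = np.einsum("bol,bkl->ok", gmat, cols).reshape(weight.data.shape)
        db = gmat.sum(axis=(0, 2))
        dcols = np.einsum("ok,bol->bkl", wmat, gmat)
        dx = _col2im(dcols, x.data.shape, kh, kw, pad, out_hw)
        return [(x, dx), (weight, dW), (bias, db)]

    return Tensor(out_data, parents=(x, weight, bias), backward=bwd)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling (H, W divisible by k)."""
    B, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by pool {k}")
    ho, wo = H // k, W // k
    windows = (x.data.reshape(B, C, ho, k, wo, k)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(B, C, ho, wo, k * k))
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gw = np.zeros_like(windows)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        dx = (gw.reshape(B, C, ho, wo, k, k)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(B, C, H, W))
        return [(x, dx)]

    return Tensor(out_data, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# modules

class Module:
    """Base class: recursive parameter collection over attributes."""

    training: bool = True

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        seen = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for v in vars(self).values():
            for m in _modules(v):
                m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: Iterable[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = np.asarray(s, dtype=float).reshape(p.data.shape)


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


def _modules(v):
    if isinstance(v, Module):
        yield v
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _modules(item)


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(_kaiming(rng, (d_in, d_out), d_in), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, pad: int = 1):
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (c_out, c_in, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class LSTM(Module):
    """Single-layer LSTM; returns the final hidden state.

    Gate layout in the packed weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at 1.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.wx = Tensor(_kaiming(rng, (d_in, 4 * d_hidden), d_in), requires_grad=True)
        self.wh = Tensor(_kaiming(rng, (d_hidden, 4 * d_hidden), d_hidden),
                         requires_grad=True)
        b = np.zeros(4 * d_hidden)
        b[d_hidden: 2 * d_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, d_in) -> final hidden (B, d_hidden)."""
        B, T, _ = x.data.shape
        H = self.d_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.wx + h @ self.wh + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class Adam:
    """Adam with optional step decay: lr <- lr * factor every ``decay_step`` epochs."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 decay_factor: float = 0.1, decay_step: int = 10):
        self.params = list(params)
        self.base_lr = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.decay_factor = decay_factor
        self.decay_step = decay_step
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def set_epoch(self, epoch: int) -> None:
        self.lr = self.base_lr * self.decay_factor ** (epoch // self.decay_step)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
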