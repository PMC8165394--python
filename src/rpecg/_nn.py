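"""Minimal NumPy neural-network kernel: layers, autograd-by-hand, Adam.

Only what the Inception-ResNet-style classifier needs is implemented:
2-D convolution (im2col + BLAS matmul), batch normalization, ReLU, max
pooling, global average pooling, dense layers, channel-concatenating
branch containers and scaled residual blocks. Tensors are NCHW float64.
Every layer caches what its backward pass needs; ``backward`` must be
called with the upstream gradient right after the corresponding
``forward``.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Param:
    """Trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    def params(self) -> List[Param]:
        return []

    def buffers(self) -> List[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats)."""
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ------------------------------------------------------------- convolution

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    n, c, hp, wp = xp.shape
    oh = (hp - kh) // sh + 1
    ow = (wp - kw) // sw + 1
    sn, sc, srow, scol = xp.strides
    win = as_strided(
        xp, shape=(n, c, kh, kw, oh, ow),
        strides=(sn, sc, srow, scol, srow * sh, scol * sw))
    return np.ascontiguousarray(win).reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(dcols: np.ndarray, xp_shape, kh, kw, sh, sw, oh, ow):
    n, c, hp, wp = xp_shape
    dxp = np.zeros(xp_shape, dtype=np.float64)
    dwin = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += dwin[:, :, i, j]
    return dxp


class Conv2d(Module):
    """'Same'-padded 2-D convolution (odd kernel sides)."""

    def __init__(self, in_c: int, out_c: int, kh: int, kw: int,
                 stride: int = 1, rng: Optional[np.random.Generator] = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        fan_in = in_c * kh * kw
        self.W = Param(rng.standard_normal((out_c, fan_in))
                       * np.sqrt(2.0 / fan_in), "conv.W")
        self.b = Param(np.zeros(out_c), "conv.b") if bias else None
        self.in_c, self.out_c = in_c, out_c
        self.kh, self.kw, self.stride = kh, kw, stride
        self.ph, self.pw = (kh - 1) // 2, (kw - 1) // 2
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train):
        n = x.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph),
                        (self.pw, self.pw)))
        cols, oh, ow = _im2col(xp, self.kh, self.kw, self.stride, self.stride)
        out = np.tensordot(self.W.value, cols, axes=([1], [1]))  # (O, N, L)
        out = out.transpose(1, 0, 2)
        if self.b is not None:
            out += self.b.value[None, :, None]
        self._cache = (cols, xp.shape, oh, ow)
        return out.reshape(n, self.out_c, oh, ow)

    def backward(self, dout):
        cols, xp_shape, oh, ow = self._cache
        n = dout.shape[0]
        dmat = dout.reshape(n, self.out_c, oh * ow)
        self.W.grad += np.tensordot(dmat, cols, axes=([0, 2], [0, 2]))
        if self.b is not None:
            self.b.grad += dmat.sum(axis=(0, 2))
        dcols = np.tensordot(dmat, self.W.value,
                             axes=([1], [0])).transpose(0, 2, 1)
        dxp = _col2im(np.ascontiguousarray(dcols), xp_shape, self.kh, self.kw,
                      self.stride, self.stride, oh, ow)
        if self.ph or self.pw:
            return dxp[:, :, self.ph:dxp.shape[2] - self.ph or None,
                       self.pw:dxp.shape[3] - self.pw or None]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dout * g * inv[None, :, None, None]
        dxhat = dout * g
        # standard batch-norm backward; means over batch+spatial axes
        dx = inv[None, :, None, None] * (
            dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx

    def __repr__(self):
        return f"BatchNorm2d({self.gamma.value.size})"


class ReLU(Module):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Module):
    def __init__(self, k: int = 3, stride: int = 2):
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2

    def forward(self, x, train):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
        n, c, hp, wp = xp.shape
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        sn, sc, sr, scol = xp.strides
        win = as_strided(xp, shape=(n, c, oh, ow, k, k),
                         strides=(sn, sc, sr * s, scol * s, sr, scol))
        flat = np.ascontiguousarray(win).reshape(n, c, oh, ow, k * k)
        self._idx = flat.argmax(axis=-1)
        self._meta = (xp.shape, x.shape, oh, ow)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        k, s, p = self.k, self.stride, self.pad
        xp_shape, x_shape, oh, ow = self._meta
        n, c = x_shape[:2]
        dflat = np.zeros((n, c, oh, ow, k * k))
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None],
                          axis=-1)
        dwin = dflat.reshape(n, c, oh, ow, k, k).transpose(0, 1, 4, 5, 2, 3)
        dxp = _col2im(dwin.reshape(n, c * k * k, oh * ow), xp_shape,
                      k, k, s, s, oh, ow)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Module):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).copy()


class Dense(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.standard_normal((n_in, n_out))
                       * np.sqrt(2.0 / n_in), "dense.W")
        self.b = Param(np.zeros(n_out), "dense.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Branches(Module):
    """Run branches on the same input, concatenate along channels."""

    def __init__(self, *branches: Module):
        self.branches = list(branches)

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def buffers(self):
        return [bb for b in self.branches for bb in b.buffers()]

    def forward(self, x, train):
        outs = [b.forward(x, train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        parts = np.split(dout, self._splits, axis=1)
        dx = None
        for b, part in zip(self.branches, parts):
            g = b.backward(np.ascontiguousarray(part))
            dx = g if dx is None else dx + g
        return dx


class ResidualInception(Module):
    """out = relu(x + scale * proj(concat(branches(x))))."""

    def __init__(self, branches: Branches, proj: Conv2d, scale: float = 0.1):
        self.branches = branches
        self.proj = proj
        self.scale = scale
        self.relu = ReLU()

    def params(self):
        return self.branches.params() + self.proj.params()

    def buffers(self):
        return self.branches.buffers() + self.proj.buffers()

    def forward(self, x, train):
        h = self.branches.forward(x, train)
        y = x + self.scale * self.proj.forward(h, train)
        return self.relu.forward(y, train)

    def backward(self, dout):
        dy = self.relu.backward(dout)
        dh = self.proj.backward(self.scale * dy)
        return dy + self.branches.backward(dh)


# ------------------------------------------------------------ loss & optim

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and gradient w.r.t. logits; y = integer labels."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adaptive-moment optimizer with the customary moment defaults."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_state(module: Module) -> List[np.ndarray]:
    """Deep copies of all parameter values and buffers, traversal order."""
    return [p.value.copy() for p in module.params()] \
        + [b.copy() for b in module.buffers()]


def set_state(module: Module, state: List[np.ndarray]) -> None:
    params = module.params()
    buffers = module.buffers()
    if len(state) != len(params) + len(buffers):
        raise ValueError("state length mismatch")
    for p, v in zip(params, state):
        p.value[...] = v
    for b, v in zip(buffers, state[len(params):]):
        b[...] = v
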