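"""Convolutional network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "conv2d",
    "Module",
    "Conv2d",
    "Sequential",
    "Upsample2",
    "Activation",
]


def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    return cols.reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, xshape: tuple, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros(xshape, dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + s * ho : s, j : j + s * wo : s] += cols[:, :, i, j]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution, x: (N,C,H,W), weight: (O,C,k,k), bias: (O,)."""
    n, c, h, w = x.shape
    o, ci, k, _ = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = _im2col(xp, k, stride, ho, wo)  # (N, C*k*k, L)
    w2 = weight.data.reshape(o, c * k * k)
    out = np.matmul(w2[None], cols)  # (N, O, L)
    out += bias.data[None, :, None]
    out = out.reshape(n, o, ho, wo)

    def backward(g):
        gl = g.reshape(n, o, ho * wo)
        gw = np.matmul(gl, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
        gb = gl.sum(axis=(0, 2))
        gcols = np.matmul(w2.T[None], gl)
        gxp = _col2im(gcols, (n, c, hp, wp), k, stride, ho, wo)
        gx = gxp[:, :, pad : hp - pad, pad : wp - pad] if pad else gxp
        return gx, gw, gb

    return Tensor._from_op(out, (x, weight, bias), backward)


class Module:
    """Base class: parameter discovery via attribute traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list, seen: set):
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                seen.add(id(value))
                params.append(value)
            elif isinstance(value, Module):
                value._collect(params, seen)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._collect(params, seen)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, arr in zip(params, state):
            p.data = np.asarray(arr, dtype=np.float32).reshape(p.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


_ACTS = {
    "relu": lambda t: t.relu(),
    "lrelu": lambda t: t.leaky_relu(0.2),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
    "none": lambda t: t,
}


class Conv2d(Module):
    """Convolution + activation; He-style init from the supplied RNG."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 act: str = "relu", rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)
        if zero_init:
            w = np.zeros((cout, cin, k, k), dtype=np.float32)
        else:
            w = rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = k // 2
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        return _ACTS[self.act](conv2d(x, self.weight, self.bias, self.stride, self.pad))


class Upsample2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.upsample2()


class Activation(Module):
    def __init__(self, act: str):
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        return _ACTS[self.act](x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N,H,W) integer labels -> (N,C,H,W) float32 one-hot."""
    n, h, w = labels.shape
    out = np.zeros((n, n_classes, h, w), dtype=np.float32)
    idx = np.arange(n)[:, None, None], labels, np.arange(h)[None, :, None], np.arange(w)[None, None, :]
    out[idx[0], labels, idx[2], idx[3]] = 1.0
    return out
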