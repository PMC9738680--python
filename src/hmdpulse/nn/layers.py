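"""Layers for the numpy autodiff backend.

Shapes follow the (N, C, H, W) / (N, C, L) channel-first convention for
convolutions and (N, T, D) for recurrent layers.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, stack

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "DepthwiseConv2d",
    "Conv1d",
    "BatchNorm",
    "AvgPool2d",
    "GlobalAvgPool2d",
    "Dropout",
    "LSTM",
    "Sequential",
    "time_resize_matrix",
]


class Module:
    """Tiny torch-like module: tracks parameters, submodules, train mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        # flat index-based dict; architecture is recreated from config
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        buffers = {}
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                buffers[f"b{j}.mean"] = m.running_mean.copy()
                buffers[f"b{j}.var"] = m.running_var.copy()
        state.update(buffers)
        return state

    def load_state_dict(self, state: dict):
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean[...] = state[f"b{j}.mean"]
                m.running_var[...] = state[f"b{j}.var"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _he_init(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def _conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int, pad: int) -> Tensor:
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    out = np.zeros((n, o, ho, wo), dtype=x.data.dtype)
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride]
            # (n,ho,wo,c) @ (c,o) -> accumulate as channels-last, move once
            out += np.moveaxis(
                np.tensordot(xs, w.data[:, :, u, v], axes=([1], [1])), 3, 1)
    out += b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for u in range(kh):
            for v in range(kw):
                xs = xp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride]
                if w.requires_grad:
                    dw[:, :, u, v] += np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                if x.requires_grad:
                    dxp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += np.moveaxis(
                        np.tensordot(g, w.data[:, :, u, v], axes=([1], [0])), 3, 1)
        if x.requires_grad:
            x._accumulate(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)
        if w.requires_grad:
            w._accumulate(dw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, (x, w, b), backward)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.weight = _he_init(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return _conv2d(x, self.weight, self.bias, self.stride, self.pad)


def _depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int, pad: int) -> Tensor:
    n, c, h, wd = x.shape
    _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    out = np.zeros((n, c, ho, wo))
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride]
            out += xs * w.data[None, :, u, v, None, None]
    out += b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for u in range(kh):
            for v in range(kw):
                xs = xp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride]
                if w.requires_grad:
                    dw[:, u, v] += (g * xs).sum(axis=(0, 2, 3))
                if x.requires_grad:
                    dxp[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += (
                        g * w.data[None, :, u, v, None, None]
                    )
        if x.requires_grad:
            x._accumulate(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)
        if w.requires_grad:
            w._accumulate(dw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, (x, w, b), backward)


class DepthwiseConv2d(Module):
    """One 2-D filter per input channel (the "Dw" convolutions)."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.weight = _he_init(rng, (channels, kernel, kernel), kernel * kernel)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return _depthwise_conv2d(x, self.weight, self.bias, self.stride, self.pad)


def _conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int, pad: int) -> Tensor:
    n, c, ln = x.shape
    o, _, k = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    lo = (ln + 2 * pad - k) // stride + 1
    out = np.zeros((n, o, lo), dtype=x.data.dtype)
    for u in range(k):
        xs = xp[:, :, u : u + stride * lo : stride]
        out += np.moveaxis(np.tensordot(xs, w.data[:, :, u], axes=([1], [1])), 2, 1)
    out += b.data[None, :, None]

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for u in range(k):
            xs = xp[:, :, u : u + stride * lo : stride]
            if w.requires_grad:
                dw[:, :, u] += np.tensordot(g, xs, axes=([0, 2], [0, 2]))
            if x.requires_grad:
                dxp[:, :, u : u + stride * lo : stride] += np.moveaxis(
                    np.tensordot(g, w.data[:, :, u], axes=([1], [0])), 2, 1)
        if x.requires_grad:
            x._accumulate(dxp[:, :, pad : pad + ln] if pad else dxp)
        if w.requires_grad:
            w._accumulate(dw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))

    return Tensor._make(out, (x, w, b), backward)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.weight = _he_init(rng, (out_ch, in_ch, kernel), in_ch * kernel)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return _conv1d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        bshape = tuple(x.shape[1] if i == 1 else 1 for i in range(x.ndim))
        gamma, beta = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            self.running_mean += self.momentum * (mu.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.reshape(-1) - self.running_var)
        else:
            mu = self.running_mean.reshape(bshape)
            var = self.running_var.reshape(bshape)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv_std
        out_data = xhat * gamma.data.reshape(bshape) + beta.data.reshape(bshape)
        training = self.training
        count = x.data.size // x.shape[1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gscaled = g * gamma.data.reshape(bshape)
                if training:
                    mean_g = gscaled.mean(axis=axes, keepdims=True)
                    mean_gx = (gscaled * xhat).mean(axis=axes, keepdims=True)
                    x._accumulate(inv_std * (gscaled - mean_g - xhat * mean_gx))
                else:
                    x._accumulate(inv_std * gscaled)

        return Tensor._make(out_data, (x, gamma, beta), backward)


class AvgPool2d(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"AvgPool2d({s}) needs divisible spatial dims, got {h}x{w}")
        return x.reshape(n, c, h // s, s, w // s, s).mean(axis=(3, 5))


class GlobalAvgPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LSTM(Module):
    """Single-layer (optionally bidirectional) LSTM over (N, T, D) input."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 bidirectional: bool = False):
        super().__init__()
        self.hidden_size = hidden_size
        self.bidirectional = bidirectional
        dirs = 2 if bidirectional else 1
        self.w_ih = [
            _he_init(rng, (input_size, 4 * hidden_size), input_size) for _ in range(dirs)
        ]
        self.w_hh = [
            _he_init(rng, (hidden_size, 4 * hidden_size), hidden_size) for _ in range(dirs)
        ]
        self.b = [Tensor(np.zeros(4 * hidden_size), requires_grad=True) for _ in range(dirs)]

    def parameters(self):
        return [*self.w_ih, *self.w_hh, *self.b]

    def _run(self, x: Tensor, direction: int) -> list[Tensor]:
        n, t, _ = x.shape
        hs = self.hidden_size
        h = Tensor(np.zeros((n, hs)))
        c = Tensor(np.zeros((n, hs)))
        steps = range(t - 1, -1, -1) if direction else range(t)
        outputs: dict[int, Tensor] = {}
        for step in steps:
            gates = x[:, step, :] @ self.w_ih[direction] + h @ self.w_hh[direction] + self.b[direction]
            i = gates[:, 0 * hs : 1 * hs].sigmoid()
            f = gates[:, 1 * hs : 2 * hs].sigmoid()
            g = gates[:, 2 * hs : 3 * hs].tanh()
            o = gates[:, 3 * hs : 4 * hs].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[step] = h
        return [outputs[step] for step in range(t)]

    def forward(self, x: Tensor) -> Tensor:
        fwd = stack(self._run(x, 0), axis=1)
        if not self.bidirectional:
            return fwd
        bwd = stack(self._run(x, 1), axis=1)
        return concat([fwd, bwd], axis=2)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def time_resize_matrix(src_len: int, dst_len: int) -> np.ndarray:
    """Fixed linear-interpolation matrix A with y = x @ A^T along time."""
    mat = np.zeros((dst_len, src_len))
    if dst_len == 1:
        mat[0] = 1.0 / src_len
        return mat
    positions = np.linspace(0, src_len - 1, dst_len)
    for row, pos in enumerate(positions):
        lo = int(np.floor(pos))
        hi = min(lo + 1, src_len - 1)
        frac = pos - lo
        mat[row, lo] += 1.0 - frac
        mat[row, hi] += frac
    return mat
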