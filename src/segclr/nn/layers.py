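"""Minimal neural-network layer library with explicit forward/backward passes.

All layers operate on float32 numpy arrays in NC(DHW) layout. Each layer
caches what it needs during ``forward`` and consumes it in ``backward``.
Parameters and their gradients are exposed through ``parameters()`` as
``(name, value, grad)`` triples; optimizers update values in place.

This is deliberately small: just the pieces needed for a 3D ResNet-18
encoder, fully connected residual classifiers, and their losses.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base class; stateless layers only need forward/backward."""

    training = True

    def parameters(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def set_training(self, flag: bool):
        self.training = flag


def _out_spatial(in_sp, k: int, stride: int, pad: int):
    return tuple((s + 2 * pad - k) // stride + 1 for s in in_sp)


def _im2col(xp: np.ndarray, k: int, stride: int, out_sp):
    """Unroll (N,C,D,H,W) into columns (N, C*k^3, n_positions)."""
    n, c = xp.shape[:2]
    od, oh, ow = out_sp
    col = np.empty((n, c, k, k, k, od, oh, ow), dtype=xp.dtype)
    s = stride
    for i in range(k):
        for j in range(k):
            for l in range(k):
                col[:, :, i, j, l] = xp[:, :, i:i + s * od:s,
                                        j:j + s * oh:s, l:l + s * ow:s]
    return col.reshape(n, c * k ** 3, od * oh * ow)


def _col2im(dcol: np.ndarray, xp_shape, k: int, stride: int, out_sp):
    """Scatter-add columns back onto the padded input volume."""
    n, c = xp_shape[:2]
    od, oh, ow = out_sp
    dxp = np.zeros(xp_shape, dtype=dcol.dtype)
    dcol = dcol.reshape(n, c, k, k, k, od, oh, ow)
    s = stride
    for i in range(k):
        for j in range(k):
            for l in range(k):
                dxp[:, :, i:i + s * od:s, j:j + s * oh:s,
                    l:l + s * ow:s] += dcol[:, :, i, j, l]
    return dxp


class Conv3d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, bias: bool = False, *, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel ** 3
        self.w = _he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in)
        self.dw = np.zeros_like(self.w)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.db = np.zeros_like(self.b) if bias else None

    def parameters(self):
        out = [("w", self.w, self.dw)]
        if self.b is not None:
            out.append(("b", self.b, self.db))
        return out

    def forward(self, x):
        k, s, p = self.k, self.stride, self.pad
        self._x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3) if p else x
        self._xp_shape = xp.shape
        self._out_sp = _out_spatial(x.shape[2:], k, s, p)
        col = _im2col(xp, k, s, self._out_sp)
        self._col = col
        wmat = self.w.reshape(self.out_ch, -1)
        y = np.matmul(wmat, col)  # (N, O, positions)
        y = y.reshape(x.shape[0], self.out_ch, *self._out_sp)
        if self.b is not None:
            y += self.b[None, :, None, None, None]
        return y

    def backward(self, grad):
        k, s, p = self.k, self.stride, self.pad
        n = self._x_shape[0]
        if self.b is not None:
            self.db[...] = grad.sum(axis=(0, 2, 3, 4))
        gmat = grad.reshape(n, self.out_ch, -1)
        # (N,O,P) x (N,P,Ck^3) summed over N -> (O,Ck^3)
        dw = np.matmul(gmat, self._col.transpose(0, 2, 1)).sum(axis=0)
        self.dw[...] = dw.reshape(self.w.shape)
        wmat = self.w.reshape(self.out_ch, -1)
        dcol = np.matmul(wmat.T, gmat)  # (N, Ck^3, P)
        dxp = _col2im(dcol, self._xp_shape, k, s, self._out_sp)
        self._col = None
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return np.ascontiguousarray(dxp)


class BatchNorm3d(Layer):
    """Affine batch normalization over (N, D, H, W) per channel."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x):
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        self._cache = (xhat, inv)
        return (self.gamma[None, :, None, None, None] * xhat
                + self.beta[None, :, None, None, None])

    def backward(self, grad):
        xhat, inv = self._cache
        axes = (0, 2, 3, 4)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = grad * self.gamma[None, :, None, None, None]
        if not self.training:
            return g * inv[None, :, None, None, None]
        gm = g.mean(axis=axes)[None, :, None, None, None]
        gxm = (g * xhat).mean(axis=axes)[None, :, None, None, None]
        dx = (g - gm - xhat * gxm) * inv[None, :, None, None, None]
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool3d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = kernel, stride, pad

    def forward(self, x):
        k, s, p = self.k, self.stride, self.pad
        self._x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3,
                    constant_values=-np.inf) if p else x
        self._xp_shape = xp.shape
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        n, c, od, oh, ow = win.shape[:5]
        flat = win.reshape(n, c, od, oh, ow, -1)
        self._arg = flat.argmax(axis=-1)
        self._out_shape = (n, c, od, oh, ow)
        return np.ascontiguousarray(flat.max(axis=-1))

    def backward(self, grad):
        k, s, p = self.k, self.stride, self.pad
        n, c, od, oh, ow = self._out_shape
        _, _, dp, hp, wp = self._xp_shape
        dxp = np.zeros((n, c, dp, hp, wp), dtype=grad.dtype).reshape(n, c, -1)
        kd, kh, kw = np.unravel_index(self._arg, (k, k, k))
        zd = np.arange(od)[None, None, :, None, None] * s
        zh = np.arange(oh)[None, None, None, :, None] * s
        zw = np.arange(ow)[None, None, None, None, :] * s
        flat_idx = ((zd + kd) * hp + (zh + kh)) * wp + (zw + kw)
        ni = np.arange(n)[:, None, None, None, None]
        ci = np.arange(c)[None, :, None, None, None]
        np.add.at(dxp, (ni, ci, flat_idx), grad)
        dxp = dxp.reshape(n, c, dp, hp, wp)
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        d, h, w = self._x_shape[2:]
        return dxp[:, :, :d, :h, :w]


class GlobalAvgPool3d(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        n, c, d, h, w = self._shape
        g = grad[:, :, None, None, None] / float(d * h * w)
        return np.broadcast_to(g, self._shape).copy()


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True, *,
                 rng: np.random.Generator):
        self.w = _he_init(rng, (in_dim, out_dim), in_dim)
        self.dw = np.zeros_like(self.w)
        self.b = np.zeros(out_dim, dtype=np.float32) if bias else None
        self.db = np.zeros_like(self.b) if bias else None

    def parameters(self):
        out = [("w", self.w, self.dw)]
        if self.b is not None:
            out.append(("b", self.b, self.db))
        return out

    def forward(self, x):
        self._x = x
        y = x @ self.w
        if self.b is not None:
            y += self.b
        return y

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        if self.b is not None:
            self.db[...] = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        out = []
        for i, lay in enumerate(self.layers):
            for name, v, g in lay.parameters():
                out.append((f"{i}.{name}", v, g))
        return out

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad

    def set_training(self, flag: bool):
        for lay in self.layers:
            lay.set_training(flag)


class BasicBlock3d(Layer):
    """Two 3x3x3 convolutions with identity or 1x1x1-projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, *, rng: np.random.Generator):
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm3d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = BatchNorm3d(out_ch)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down: Sequential | None = Sequential(
                Conv3d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng),
                BatchNorm3d(out_ch))
        else:
            self.down = None

    def parameters(self):
        parts = [("conv1", self.conv1), ("bn1", self.bn1),
                 ("conv2", self.conv2), ("bn2", self.bn2)]
        if self.down is not None:
            parts.append(("down", self.down))
        out = []
        for pname, lay in parts:
            for name, v, g in lay.parameters():
                out.append((f"{pname}.{name}", v, g))
        return out

    def forward(self, x):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        h = self.bn2.forward(self.conv2.forward(h))
        sc = x if self.down is None else self.down.forward(x)
        return self.relu2.forward(h + sc)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        gh = self.bn2.backward(g)
        gh = self.conv2.backward(gh)
        gh = self.bn1.backward(self.relu1.backward(gh))
        gh = self.conv1.backward(gh)
        gs = g if self.down is None else self.down.backward(g)
        return gh + gs

    def set_training(self, flag: bool):
        for lay in (self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
                    self.relu2):
            lay.set_training(flag)
        if self.down is not None:
            self.down.set_training(flag)


def parameter_count(layer: Layer) -> int:
    return int(sum(v.size for _, v, _ in layer.parameters()))


def get_state(layer: Layer) -> dict[str, np.ndarray]:
    """All arrays needed to restore the layer: parameters + BN running stats."""
    state = {name: v.copy() for name, v, _ in layer.parameters()}
    for name, bn in _iter_batchnorms(layer):
        state[f"{name}::running_mean"] = bn.running_mean.copy()
        state[f"{name}::running_var"] = bn.running_var.copy()
    return state


def set_state(layer: Layer, state: dict[str, np.ndarray]) -> None:
    for name, v, _ in layer.parameters():
        v[...] = state[name]
    for name, bn in _iter_batchnorms(layer):
        bn.running_mean[...] = state[f"{name}::running_mean"]
        bn.running_var[...] = state[f"{name}::running_var"]


def _iter_batchnorms(layer: Layer, prefix: str = ""):
    if isinstance(layer, BatchNorm3d):
        yield prefix or "bn", layer
    elif isinstance(layer, Sequential):
        for i, sub in enumerate(layer.layers):
            yield from _iter_batchnorms(sub, f"{prefix}{i}.")
    elif isinstance(layer, BasicBlock3d):
        yield f"{prefix}bn1", layer.bn1
        yield f"{prefix}bn2", layer.bn2
        if layer.down is not None:
            yield from _iter_batchnorms(layer.down, f"{prefix}down.")
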