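"""Convolutional, normalization, activation and pooling layers.

Convolutions accumulate one BLAS matmul per kernel offset instead of
materializing a full im2col matrix; at the clip sizes this package
trains on (tens of pixels per side) that keeps both memory and Python
overhead small.
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import Module, Parameter


def _tuplify(value, n: int) -> tuple[int, ...]:
    if isinstance(value, (tuple, list)):
        if len(value) != n:
            raise ValueError(f"expected length-{n} tuple, got {value!r}")
        return tuple(int(v) for v in value)
    return (int(value),) * n


class Conv(Module):
    """N-dimensional cross-correlation (N = 2 or 3 spatial axes)."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, padding=0,
                 groups=1, bias=False, ndim=3):
        super().__init__()
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.ndim = int(ndim)
        self.kernel = _tuplify(kernel, ndim)
        self.stride = _tuplify(stride, ndim)
        self.padding = _tuplify(padding, ndim)
        self.groups = int(groups)
        if in_channels % self.groups or out_channels % self.groups:
            raise ValueError("channels must divide groups")
        self.icg = in_channels // self.groups
        self.ocg = out_channels // self.groups
        self.weight = Parameter((out_channels, self.icg, *self.kernel))
        self.bias = Parameter((out_channels,)) if bias else None

    def reset_parameters(self, rng: np.random.Generator) -> None:
        fan_in = self.icg * int(np.prod(self.kernel))
        std = np.sqrt(2.0 / fan_in)
        self.weight.data = rng.standard_normal(
            self.weight.shape, dtype=np.float32) * np.float32(std)
        if self.bias is not None:
            self.bias.data[...] = 0.0

    def _out_shape(self, spatial):
        return tuple(
            (s + 2 * p - k) // st + 1
            for s, p, k, st in zip(spatial, self.padding, self.kernel, self.stride))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != self.ndim + 2 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"conv expected (B, {self.in_channels}, {'x'.join('S' * self.ndim)}) "
                f"input, got shape {x.shape}")
        B = x.shape[0]
        spatial = x.shape[2:]
        out_sp = self._out_shape(spatial)
        if any(o <= 0 for o in out_sp):
            raise ValueError(f"kernel {self.kernel} larger than padded input {spatial}")
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        xp = np.pad(x, pad) if any(self.padding) else x
        P = int(np.prod(out_sp))
        out = np.zeros((B, self.out_channels, P), dtype=np.float32)
        w = self.weight.data
        for g in range(self.groups):
            ic = slice(g * self.icg, (g + 1) * self.icg)
            oc = slice(g * self.ocg, (g + 1) * self.ocg)
            for offs in itertools.product(*(range(k) for k in self.kernel)):
                sl = tuple(slice(o, o + st * n, st)
                           for o, st, n in zip(offs, self.stride, out_sp))
                xs = xp[(slice(None), ic) + sl].reshape(B, self.icg, P)
                w_o = w[(oc, slice(None)) + offs]  # (ocg, icg)
                out[:, oc] += w_o[None] @ xs
        out = out.reshape(B, self.out_channels, *out_sp)
        if self.bias is not None:
            out += self.bias.data.reshape((1, -1) + (1,) * self.ndim)
        self._cache = (xp, x.shape, out_sp)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, x_shape, out_sp = self._cache
        B = grad.shape[0]
        P = int(np.prod(out_sp))
        gflat = grad.reshape(B, self.out_channels, P).astype(np.float32, copy=False)
        dxp = np.zeros_like(xp, dtype=np.float32)
        w = self.weight.data
        for g in range(self.groups):
            ic = slice(g * self.icg, (g + 1) * self.icg)
            oc = slice(g * self.ocg, (g + 1) * self.ocg)
            gg = gflat[:, oc]
            for offs in itertools.product(*(range(k) for k in self.kernel)):
                sl = tuple(slice(o, o + st * n, st)
                           for o, st, n in zip(offs, self.stride, out_sp))
                xs = xp[(slice(None), ic) + sl].reshape(B, self.icg, P)
                widx = (oc, slice(None)) + offs
                # dW[o, c] = sum_{b,p} g[b,o,p] x[b,c,p]
                self.weight.grad[widx] += np.tensordot(gg, xs, axes=([0, 2], [0, 2]))
                # dX contribution: w^T g
                contrib = (w[widx].T[None] @ gg).reshape(B, self.icg, *out_sp)
                dxp[(slice(None), ic) + sl] += contrib
        if self.bias is not None:
            self.bias.grad += gflat.sum(axis=(0, 2))
        if any(self.padding):
            core = tuple(slice(p, p + s) for p, s in zip(self.padding, x_shape[2:]))
            return dxp[(slice(None), slice(None)) + core]
        return dxp


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (1)."""

    buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = int(num_features)
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Parameter((num_features,))
        self.beta = Parameter((num_features,))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def reset_parameters(self, rng: np.random.Generator) -> None:
        self.gamma.data[...] = 1.0
        self.beta.data[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def _bshape(self, ndim):
        return (1, self.num_features) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape)
        return self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gs = self.gamma.data.reshape(shape) * inv.reshape(shape)
        if not self.training:
            return grad * gs
        n = grad.size // self.num_features
        mean_g = grad.mean(axis=axes).reshape(shape)
        mean_gx = (grad * xhat).sum(axis=axes).reshape(shape) / n
        return gs * (grad - mean_g - xhat * mean_gx)


class ReLU(Module):
    """ReLU with an optional guided-backprop mode.

    In guided mode the backward pass additionally zeroes negative
    incoming gradients, the deconv-style modification used by guided
    grad-CAM.
    """

    def __init__(self):
        super().__init__()
        self.guided = False

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        out = grad * self._mask
        if self.guided:
            out = out * (grad > 0)
        return out


class Sigmoid(Module):
    def forward(self, x):
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Swish(Module):
    """x * sigmoid(x) (the inner activation of X3D bottlenecks)."""

    def forward(self, x):
        sig = 1.0 / (1.0 + np.exp(-x))
        self._cache = (x, sig)
        return x * sig

    def backward(self, grad):
        x, sig = self._cache
        return grad * (sig + x * sig * (1.0 - sig))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = int(in_features)
        self.out_features = int(out_features)
        self.weight = Parameter((out_features, in_features))
        self.bias = Parameter((out_features,)) if bias else None

    def reset_parameters(self, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / self.in_features)
        self.weight.data = rng.standard_normal(
            self.weight.shape, dtype=np.float32) * np.float32(std)
        if self.bias is not None:
            self.bias.data[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out = out + self.bias.data
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class GlobalAvgPool(Module):
    """Mean over every axis after the channel axis: (B, C, *S) -> (B, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, grad):
        shape = self._shape
        n = int(np.prod(shape[2:]))
        return np.broadcast_to(
            grad.reshape(shape[:2] + (1,) * (len(shape) - 2)), shape) / n


class SqueezeExcite(Module):
    """Channel gating: x * sigmoid(W2 relu(W1 gap(x)))."""

    def __init__(self, channels: int, reduced: int):
        super().__init__()
        self.fc1 = Linear(channels, reduced, bias=True)
        self.fc2 = Linear(reduced, channels, bias=True)

    def forward(self, x):
        axes = tuple(range(2, x.ndim))
        pooled = x.mean(axis=axes)                      # (B, C)
        h = self.fc1(pooled)
        hr = np.maximum(h, 0.0)
        s = 1.0 / (1.0 + np.exp(-self.fc2(hr)))         # (B, C)
        shape = s.shape + (1,) * len(axes)
        self._cache = (x, h, hr, s, axes, shape)
        return x * s.reshape(shape)

    def backward(self, grad):
        x, h, hr, s, axes, shape = self._cache
        ds = (grad * x).sum(axis=axes) * s * (1.0 - s)
        dhr = self.fc2.backward(ds)
        dpooled = self.fc1.backward(dhr * (h > 0))
        n = int(np.prod(x.shape[2:]))
        dx = grad * s.reshape(shape)
        dx += np.broadcast_to(dpooled.reshape(shape), x.shape) / n
        return dx


class ResBlock(Module):
    """main(x) + shortcut(x), followed by an activation."""

    def __init__(self, main: Module, shortcut: Module | None = None):
        super().__init__()
        self.main = main
        self.shortcut = shortcut
        self.act = ReLU()

    def forward(self, x):
        y = self.main(x)
        r = self.shortcut(x) if self.shortcut is not None else x
        return self.act(y + r)

    def backward(self, grad):
        g = self.act.backward(grad)
        gx = self.main.backward(g)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(g)
        else:
            gx = gx + g
        return gx
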