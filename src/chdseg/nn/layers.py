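"""Minimal NumPy neural-network layers with hand-written backpropagation.

All tensors are NCHW ``float32`` arrays.  Each layer implements
``forward(x)`` and ``backward(grad_out)``; the forward pass caches whatever
the backward pass needs.  Every layer is exercised by numerical
gradient-check tests, which are the correctness oracle for this module.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: parameter bookkeeping plus a train/eval switch."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    __call__ = lambda self, x: self.forward(x)


# ---------------------------------------------------------------------------
# initialisation


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def gaussian_init(rng: np.random.Generator, shape: tuple, std: float) -> np.ndarray:
    return (rng.normal(0.0, std, size=shape)).astype(DTYPE)


# ---------------------------------------------------------------------------
# convolution primitives


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    # view of shape (N, C, Ho, Wo, k, k)
    v = sliding_window_view(xp, (k, k), axis=(2, 3))
    return v[:, :, ::s, ::s]


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 init: str = "glorot", init_std: float = 0.1414) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        shape = (out_ch, in_ch, kernel, kernel)
        if init == "glorot":
            w = glorot_uniform(rng, shape, in_ch * kernel * kernel, out_ch * kernel * kernel)
        else:
            w = gaussian_init(rng, shape, init_std)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch))
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        xp = _pad(x.astype(DTYPE, copy=False), p)
        win = _windows(xp, k, s)
        out = np.einsum("nchwij,ocij->nohw", win, self.weight.value, optimize=True)
        out += self.bias.value[None, :, None, None]
        self._cache = (x.shape, xp)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        x_shape, xp = self._cache
        win = _windows(xp, k, s)
        self.weight.grad += np.einsum("nchwij,nohw->ocij", win, grad, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        Ho, Wo = grad.shape[2], grad.shape[3]
        W = self.weight.value
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += np.einsum(
                    "nohw,oc->nchw", grad, W[:, :, i, j], optimize=True)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp.reshape(x_shape)


class ConvTranspose2d(Module):
    """Fractionally-strided convolution; out = (in-1)*stride - 2*pad + kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 init: str = "glorot", init_std: float = 0.1414) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        shape = (in_ch, out_ch, kernel, kernel)
        if init == "glorot":
            w = glorot_uniform(rng, shape, in_ch * kernel * kernel, out_ch * kernel * kernel)
        else:
            w = gaussian_init(rng, shape, init_std)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch))
        self._cache: np.ndarray | None = None

    def out_size(self, n: int) -> int:
        return (n - 1) * self.stride - 2 * self.padding + self.kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        x = x.astype(DTYPE, copy=False)
        N, _, H, W_ = x.shape
        Ho, Wo = self.out_size(H), self.out_size(W_)
        outp = np.zeros((N, self.out_ch, Ho + 2 * p, Wo + 2 * p), dtype=DTYPE)
        V = self.weight.value
        for i in range(k):
            for j in range(k):
                outp[:, :, i:i + s * H:s, j:j + s * W_:s] += np.einsum(
                    "nihw,io->nohw", x, V[:, :, i, j], optimize=True)
        out = outp[:, :, p:p + Ho, p:p + Wo] if p else outp
        out = out + self.bias.value[None, :, None, None]
        self._cache = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        x = self._cache
        gp = _pad(grad.astype(DTYPE, copy=False), p)
        win = _windows(gp, k, s)  # (N, out_ch, H, W, k, k)
        self.weight.grad += np.einsum("nchw,nohwab->coab", x, win, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        dx = np.einsum("nohwab,coab->nchw", win, self.weight.value, optimize=True)
        return dx


class MaxPool2d(Module):
    """Non-overlapping max pooling; input padded with -inf up to a multiple
    of the pool size, so any spatial extent is accepted (ceil semantics)."""

    def __init__(self, size: int) -> None:
        super().__init__()
        self.size = size
        self._cache: tuple | None = None

    def out_size(self, n: int) -> int:
        return -(-n // self.size)

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        N, C, H, W = x.shape
        Ho, Wo = self.out_size(H), self.out_size(W)
        ph, pw = Ho * s - H, Wo * s - W
        xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                    constant_values=-np.inf)
        v = xp.reshape(N, C, Ho, s, Wo, s).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(N, C, Ho, Wo, s * s)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, (ph, pw), idx)
        return out.astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        s = self.size
        (N, C, H, W), (ph, pw), idx = self._cache
        Ho, Wo = grad.shape[2], grad.shape[3]
        dv = np.zeros((N, C, Ho, Wo, s * s), dtype=DTYPE)
        np.put_along_axis(dv, idx[..., None], grad[..., None].astype(DTYPE), axis=-1)
        dxp = dv.reshape(N, C, Ho, Wo, s, s).transpose(0, 1, 2, 4, 3, 5)
        dxp = dxp.reshape(N, C, Ho * s, Wo * s)
        return dxp[:, :, :H, :W]


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return out.astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        N, _, H, W = shape
        m = N * H * W
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = grad * g
        if not self.training:
            return (dxhat * inv[None, :, None, None]).astype(DTYPE)
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (m * dxhat - t1 - xhat * t2)
        return dx.astype(DTYPE)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(DTYPE)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad).astype(DTYPE)


class Tanh(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = np.tanh(x).astype(DTYPE)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return (grad * (1.0 - self._out ** 2)).astype(DTYPE)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._out = (1.0 / (1.0 + np.exp(-x))).astype(DTYPE)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return (grad * self._out * (1.0 - self._out)).astype(DTYPE)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return (x * self._mask).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(DTYPE)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def center_crop_map(x: np.ndarray, target_h: int, target_w: int) -> tuple[np.ndarray, tuple]:
    """Centered spatial crop of a feature map; returns (cropped, offsets)."""
    H, W = x.shape[2], x.shape[3]
    oh, ow = (H - target_h) // 2, (W - target_w) // 2
    return x[:, :, oh:oh + target_h, ow:ow + target_w], (oh, ow, H, W)


def uncrop_grad(grad: np.ndarray, offsets: tuple) -> np.ndarray:
    oh, ow, H, W = offsets
    out = np.zeros((grad.shape[0], grad.shape[1], H, W), dtype=DTYPE)
    out[:, :, oh:oh + grad.shape[2], ow:ow + grad.shape[3]] = grad
    return out
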