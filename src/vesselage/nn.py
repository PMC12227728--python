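"""Minimal CPU neural-network engine (numpy, NCHW layout).

Implements exactly the layer set needed by the fusion classifier and its
convolutional backbones: convolution (dense and depthwise), batch
normalisation (inference-mode affine), ReLU/ReLU6, max/average pooling,
global average pooling, flatten, linear, dropout — each with a hand-written
backward pass — plus an Adam optimiser and a numerically stable binary
cross-entropy on logits.  Every layer records its most recent output and
output-gradient, which is what Grad-CAM reads.

Conventions: activations are ``(N, C, H, W)`` float arrays; parameters are
held in :class:`Param` objects with a ``trainable`` flag — frozen parameters
receive no gradient updates and are bit-identical before and after training.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A tensor parameter with an accumulated gradient and a frozen flag."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True) -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: forward/backward with cached activations."""

    def __init__(self) -> None:
        self.last_output: np.ndarray | None = None
        self.last_output_grad: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def sublayers(self) -> list[tuple[str, "Layer"]]:
        return []

    def named_layers(self, prefix: str = "") -> Iterable[tuple[str, "Layer"]]:
        yield prefix.rstrip("."), self
        for name, sub in self.sublayers():
            yield from sub.named_layers(f"{prefix}{name}.")

    def set_frozen(self, frozen: bool) -> None:
        for p in self.params():
            p.trainable = not frozen
        for _name, sub in self.sublayers():
            sub.set_frozen(frozen)

    def all_params(self) -> list[Param]:
        out = list(self.params())
        for _name, sub in self.sublayers():
            out.extend(sub.all_params())
        return out


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    """2D convolution; ``groups`` of 1 (dense) or ``cin`` (depthwise)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        if groups not in (1, cin):
            raise ValueError("only dense (groups=1) or depthwise (groups=cin) convs supported")
        if groups == cin and cout != cin:
            raise ValueError("depthwise conv requires cout == cin")
        self.cin, self.cout, self.k, self.stride, self.pad, self.groups = (
            cin, cout, k, stride, pad, groups,
        )
        rng = rng or np.random.default_rng(0)
        cpg = cin // groups  # channels per group
        self.weight = Param(he_init(rng, (cout, cpg, k, k), cpg * k * k, dtype))
        self.bias = Param(np.zeros(cout, dtype=dtype)) if bias else None
        self._cols: np.ndarray | None = None  # depthwise path
        self._colmat: np.ndarray | None = None  # dense path, (N*Ho*Wo, C*k*k)
        self._dims: tuple[int, ...] | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p, k, s = self.pad, self.k, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        wins = sliding_window_view(x, (k, k), axis=(2, 3))
        return wins[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._xshape = x.shape
        cols = self._im2col(x)
        n, c, ho, wo, k, _ = cols.shape
        self._dims = (n, c, ho, wo, k)
        w = self.weight.value
        if self.groups == 1:
            mat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
            self._colmat = mat  # reused by backward for the weight gradient
            self._cols = None
            out = (mat @ w.reshape(self.cout, -1).T).reshape(n, ho, wo, self.cout)
            out = out.transpose(0, 3, 1, 2)
        else:  # depthwise
            self._cols = cols
            self._colmat = None
            out = np.einsum("nchwij,cij->nchw", cols, w[:, 0], optimize=True)
        if self.bias is not None:
            out = out + self.bias.value[None, :, None, None]
        out = np.ascontiguousarray(out)
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        assert self._dims is not None and self._xshape is not None
        n, c, ho, wo, k = self._dims
        w = self.weight.value
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        if self.groups == 1:
            colmat = self._colmat
            assert colmat is not None
            gymat = gy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
            self.weight.grad += (gymat.T @ colmat).reshape(w.shape)
            dcol = (gymat @ w.reshape(self.cout, -1)).reshape(n, ho, wo, c, k, k)
            dcol = dcol.transpose(0, 3, 1, 2, 4, 5)
        else:
            cols = self._cols
            assert cols is not None
            self.weight.grad += np.einsum("nchw,nchwij->cij", gy, cols, optimize=True)[:, None]
            dcol = gy[:, :, :, :, None, None] * w[:, 0][None, :, None, None, :, :]
        # scatter-add columns back into the (padded) input gradient
        nh, nw = self._xshape[2], self._xshape[3]
        p, s = self.pad, self.stride
        gx = np.zeros((n, self.cin, nh + 2 * p, nw + 2 * p), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcol[:, :, :, :, i, j]
        if p:
            gx = gx[:, :, p:-p, p:-p]
        self._cols = None
        self._colmat = None
        return gx


class BatchNorm2d(Layer):
    """Inference-mode batch normalisation (affine with running statistics).

    Pretrained running statistics are part of the checkpoint; without them
    (random init) the layer is the identity up to the learnable affine.
    The frozen-statistics behaviour matches fine-tuning practice where only
    downstream layers are trained.
    """

    def __init__(self, c: int, eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps = eps
        self._xhat: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _scale(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.running_var + self.eps)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xhat = (x - self.running_mean[None, :, None, None]) * self._scale()[None, :, None, None]
        self._xhat = xhat
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        assert self._xhat is not None
        self.gamma.grad += (gy * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gx = gy * (self.gamma.value * self._scale())[None, :, None, None]
        self._xhat = None
        return gx


class ReLU(Layer):
    def __init__(self, cap: float | None = None) -> None:
        super().__init__()
        self.cap = cap
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if self.cap is not None:
            out = np.minimum(out, self.cap)
            self._mask = (x > 0.0) & (x < self.cap)
        else:
            self._mask = x > 0.0
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        assert self._mask is not None
        gx = gy * self._mask
        self._mask = None
        return gx


def ReLU6() -> ReLU:
    return ReLU(cap=6.0)


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling (odd trailing rows/columns are cropped)."""

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : h2 * 2, : w2 * 2]
        win = xc.reshape(n, c, h2, 2, w2, 2)
        out = win.max(axis=(3, 5))
        self._cache = (x.shape, win, out)
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        assert self._cache is not None
        xshape, win, out = self._cache
        mask = win == out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = mask * (gy[:, :, :, None, :, None] / counts)
        n, c, h, w = xshape
        gx = np.zeros(xshape, dtype=gy.dtype)
        h2, w2 = h // 2, w // 2
        gx[:, :, : h2 * 2, : w2 * 2] = g.reshape(n, c, h2 * 2, w2 * 2)
        self._cache = None
        return gx


class AvgPool2d(Layer):
    """Non-overlapping k x k average pooling (exact when k divides H, W)."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.k
        n, c, h, w = x.shape
        h2, w2 = h // k, w // k
        xc = x[:, :, : h2 * k, : w2 * k]
        out = xc.reshape(n, c, h2, k, w2, k).mean(axis=(3, 5))
        self._xshape = x.shape
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        assert self._xshape is not None
        k = self.k
        n, c, h, w = self._xshape
        h2, w2 = h // k, w // k
        gx = np.zeros(self._xshape, dtype=gy.dtype)
        g = np.repeat(np.repeat(gy, k, axis=2), k, axis=3) / (k * k)
        gx[:, :, : h2 * k, : w2 * k] = g
        self._xshape = None
        return gx


class GlobalAvgPool(Layer):
    """Spatial mean: (N, C, H, W) -> (N, C)."""

    def __init__(self) -> None:
        super().__init__()
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._xshape = x.shape
        out = x.mean(axis=(2, 3))
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        assert self._xshape is not None
        n, c, h, w = self._xshape
        gx = np.broadcast_to(gy[:, :, None, None] / (h * w), self._xshape).astype(gy.dtype)
        self._xshape = None
        return np.ascontiguousarray(gx)


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._xshape = x.shape
        out = x.reshape(x.shape[0], -1)
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        assert self._xshape is not None
        return gy.reshape(self._xshape)


class Linear(Layer):
    def __init__(
        self,
        din: int,
        dout: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Param(he_init(rng, (dout, din), din, dtype))
        self.bias = Param(np.zeros(dout, dtype=dtype))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        out = x @ self.weight.value.T + self.bias.value
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        assert self._x is not None
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        gx = gy @ self.weight.value
        self._x = None
        return gx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, seed: int = 0) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(seed)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            self.last_output = x
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        self._mask = mask.astype(x.dtype)
        out = x * self._mask
        self.last_output = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        if self._mask is None:
            return gy
        return gy * self._mask


class Sequential(Layer):
    """Ordered container of named layers."""

    def __init__(self, layers: Sequence[tuple[str, Layer]]) -> None:
        super().__init__()
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names in Sequential")
        self.layers: list[tuple[str, Layer]] = list(layers)

    def sublayers(self) -> list[tuple[str, Layer]]:
        return list(self.layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for _name, layer in self.layers:
            x = layer.forward(x, train=train)
        self.last_output = x
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.last_output_grad = gy
        for _name, layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def find(self, path: str) -> Layer:
        """Resolve a dotted layer path (e.g. ``stage2.block4.conv3``)."""
        for name, layer in self.named_layers():
            if name == path:
                return layer
        available = sorted(n for n, _ in self.named_layers() if n)
        raise KeyError(f"no layer named {path!r}; available: {available}")

    def split(self, cut: str) -> tuple["Sequential", "Sequential"]:
        """Split into (prefix, suffix); the suffix starts at top-level layer ``cut``."""
        names = [n for n, _ in self.layers]
        if cut not in names:
            raise KeyError(f"no top-level layer named {cut!r}; available: {names}")
        i = names.index(cut)
        return Sequential(self.layers[:i]), Sequential(self.layers[i:])


class Adam:
    """Adam optimiser over the trainable subset of a parameter list."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = [p for p in params if p.trainable]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz
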