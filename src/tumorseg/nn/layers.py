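"""Layers with forward/backward passes. Tensors are NCHW float32.

Convolutions use im2col/col2im; 'same' padding follows the convention
``pad_total = max((ceil(n/s) - 1) * s + k - n, 0)`` with the extra pixel on
the bottom/right, which keeps the stem's spatial arithmetic exact
(256 -> 128 -> 64 -> 32 -> 10 through the default network).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2D",
    "AvgPool2D",
    "Flatten",
    "Dense",
    "Sequential",
    "IdentityBlock",
    "ConvBlock",
    "InceptionBlock",
]


class Param:
    """A tensor of weights with its gradient and optimizer slot storage."""

    __slots__ = ("name", "value", "grad", "trainable", "state")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.state: dict = {}

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    def params(self) -> list[Param]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def iter_layers(self):
        yield self
        for child in self.children():
            yield from child.iter_layers()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pads(n: int, k: int, s: int) -> tuple[int, int]:
    total = max((int(np.ceil(n / s)) - 1) * s + k - n, 0)
    return total // 2, total - total // 2


def _out_size(n: int, k: int, s: int, padding: str) -> int:
    if padding == "same":
        return int(np.ceil(n / s))
    return (n - k) // s + 1


def _im2col(x: np.ndarray, k: int, s: int, padding: str) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    if padding == "same":
        pt, pb = _same_pads(h, k, s)
        pl, pr = _same_pads(w, k, s)
        x = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    else:
        pt = pl = 0
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // s + 1
    wo = (wp - k) // s + 1
    shape = (n, c, k, k, ho, wo)
    strides = (
        x.strides[0], x.strides[1],
        x.strides[2], x.strides[3],
        x.strides[2] * s, x.strides[3] * s,
    )
    cols = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    cols = np.ascontiguousarray(cols.transpose(0, 4, 5, 1, 2, 3)).reshape(
        n * ho * wo, c * k * k
    )
    return cols, (n, c, h, w, hp, wp, ho, wo, pt, pl)


def _col2im(dcols: np.ndarray, meta: tuple, k: int, s: int) -> np.ndarray:
    n, c, h, w, hp, wp, ho, wo, pt, pl = meta
    dx_pad = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dx_pad[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
    return dx_pad[:, :, pt : pt + h, pl : pl + w]


class Conv2D(Layer):
    """2-D convolution with He-initialized weights."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        stride: int = 1,
        padding: str = "same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        w = rng.standard_normal((cout, cin, kernel, kernel)) * np.sqrt(2.0 / fan_in)
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.cin, self.cout = cin, cout
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False):
        if self.kernel == 1:  # pointwise conv: plain channel matmul, no im2col
            xs = x[:, :, :: self.stride, :: self.stride]
            n, c, ho, wo = xs.shape
            cols = xs.transpose(0, 2, 3, 1).reshape(-1, c)
            out = cols @ self.w.value.reshape(self.cout, c).T
            if self.b is not None:
                out += self.b.value
            self._cache = (cols, ("pointwise", x.shape, (n, ho, wo)))
            return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        cols, meta = _im2col(x, self.kernel, self.stride, self.padding)
        wmat = self.w.value.reshape(self.cout, -1)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b.value
        n, _, _, _, _, _, ho, wo, _, _ = meta
        self._cache = (cols, meta)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, meta = self._cache
        if self.kernel == 1:
            _, xshape, (n, ho, wo) = meta
            dmat = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
            self.w.grad = (dmat.T @ cols).reshape(self.w.value.shape)
            if self.b is not None:
                self.b.grad = dmat.sum(axis=0)
            dcols = dmat @ self.w.value.reshape(self.cout, -1)
            dx = np.zeros(xshape, dtype=dy.dtype)
            dx[:, :, :: self.stride, :: self.stride] = (
                dcols.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
            )
            return dx
        n, _, _, _, _, _, ho, wo, _, _ = meta
        dmat = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.w.grad = (dmat.T @ cols).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad = dmat.sum(axis=0)
        dcols = dmat @ self.w.value.reshape(self.cout, -1)
        return _col2im(dcols, meta, self.kernel, self.stride)


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics.

    Carries 2 trainable (scale, shift) and 2 non-trainable (running mean,
    running variance) parameters per channel.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = Param(f"{name}.mean", np.zeros(channels), trainable=False)
        self.running_var = Param(f"{name}.var", np.ones(channels), trainable=False)
        self.momentum, self.eps = momentum, eps
        self._cache = None
        self._updates = 0     # for bias-corrected running averages early in training
        self._cal_n = 0       # batches seen during an explicit calibration pass
        self._collecting = False
        self._calibrated = False

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def start_calibration(self) -> None:
        """Reset stored statistics ahead of a stats-collection pass."""
        self._cal_n = 0
        self._collecting = True
        self._calibrated = False
        self.running_mean.value[:] = 0.0
        self.running_var.value[:] = 0.0

    def finish_calibration(self) -> None:
        self._collecting = False
        self._calibrated = True

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._collecting:
                # cumulative plain average during calibration
                n = self._cal_n
                self.running_mean.value = ((n * self.running_mean.value + mean) / (n + 1)).astype(np.float32)
                self.running_var.value = ((n * self.running_var.value + var) / (n + 1)).astype(np.float32)
                self._cal_n += 1
            else:
                m = self.momentum
                self.running_mean.value = (m * self.running_mean.value + (1 - m) * mean).astype(np.float32)
                self.running_var.value = (m * self.running_var.value + (1 - m) * var).astype(np.float32)
                self._updates += 1
        elif self._calibrated:
            mean, var = self.running_mean.value, self.running_var.value
        elif self._updates > 0:
            # debias the exponential averages (they start from 0 mean / unit var)
            corr = 1.0 - self.momentum ** self._updates
            mean = self.running_mean.value / corr
            var = (self.running_var.value - self.momentum**self._updates) / corr
            var = np.maximum(var, 0.0)
        else:
            mean, var = self.running_mean.value, self.running_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, inv, shape = self._cache
        n_el = shape[0] * shape[2] * shape[3]
        self.gamma.grad = (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_el
        ) * inv[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2D(Layer):
    def __init__(self, kernel: int, stride: int, padding: str = "same"):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n * c, 1, h, w)
        if self.padding == "same":
            # pad with -inf so padding never wins the max
            pt, pb = _same_pads(h, self.kernel, self.stride)
            pl, pr = _same_pads(w, self.kernel, self.stride)
            xr = np.pad(xr, ((0, 0), (0, 0), (pt, pb), (pl, pr)),
                        constant_values=-np.inf)
            cols, meta = _im2col(xr, self.kernel, self.stride, "valid")
            meta = (meta[0], meta[1], h, w, meta[4], meta[5], meta[6], meta[7], pt, pl)
        else:
            cols, meta = _im2col(xr, self.kernel, self.stride, "valid")
        self._argmax = cols.argmax(axis=1)
        self._meta = meta
        out = cols[np.arange(cols.shape[0]), self._argmax]
        _, _, _, _, _, _, ho, wo, _, _ = meta
        return out.reshape(n, ho, wo, c).transpose(0, 3, 1, 2) if False else out.reshape(
            n * c, ho, wo
        ).reshape(n, c, ho, wo)

    def backward(self, dy):
        meta = self._meta
        _, _, h, w, hp, wp, ho, wo, pt, pl = meta
        nc = dy.shape[0] * dy.shape[1]
        dcols = np.zeros((nc * ho * wo, self.kernel * self.kernel), dtype=dy.dtype)
        dcols[np.arange(nc * ho * wo), self._argmax] = dy.reshape(-1)
        meta_unpad = (nc, 1, hp, wp, hp, wp, ho, wo, 0, 0)
        dx_pad = _col2im(dcols, meta_unpad, self.kernel, self.stride)
        dx = dx_pad[:, :, pt : pt + h, pl : pl + w]
        return dx.reshape(dy.shape[0], dy.shape[1], h, w)


class AvgPool2D(Layer):
    def __init__(self, kernel: int, stride: int, padding: str = "valid"):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        xr = x.reshape(n * c, 1, h, w)
        cols, meta = _im2col(xr, self.kernel, self.stride, self.padding)
        self._meta = meta
        out = cols.mean(axis=1)
        _, _, _, _, _, _, ho, wo, _, _ = meta
        self._shape = (n, c, h, w)
        return out.reshape(n, c, ho, wo)

    def backward(self, dy):
        meta = self._meta
        n, c, h, w = self._shape
        _, _, _, _, _, _, ho, wo, _, _ = meta
        k2 = self.kernel * self.kernel
        dcols = np.repeat(dy.reshape(-1, 1), k2, axis=1) / k2
        dx = _col2im(dcols, meta, self.kernel, self.stride)
        return dx.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None,
                 name: str = "dense"):
        rng = rng if rng is not None else np.random.default_rng(0)
        w = rng.standard_normal((nin, nout)) * np.sqrt(2.0 / nin)
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(nout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad = self._x.T @ dy
        self.b.grad = dy.sum(axis=0)
        return dy @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def children(self):
        return list(self.layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class IdentityBlock(Layer):
    """Residual block: 1x1(F1) -> 3x3(F2) -> 1x1(F3), post-conv batch norm.

    The input joins the main path through an additive skip; when the input
    channel count differs from F3 a 1x1 projection (with batch norm) is
    inserted on the skip.
    """

    def __init__(self, cin: int, filters: tuple[int, int, int],
                 rng: np.random.Generator | None = None, name: str = "identity"):
        f1, f2, f3 = filters
        rng = rng if rng is not None else np.random.default_rng(0)
        self.main = Sequential([
            Conv2D(cin, f1, 1, rng=rng, name=f"{name}.conv1"),
            BatchNorm2D(f1, name=f"{name}.bn1"),
            ReLU(),
            Conv2D(f1, f2, 3, rng=rng, name=f"{name}.conv2"),
            BatchNorm2D(f2, name=f"{name}.bn2"),
            ReLU(),
            Conv2D(f2, f3, 1, rng=rng, name=f"{name}.conv3"),
            BatchNorm2D(f3, name=f"{name}.bn3"),
        ])
        self.proj = None
        if cin != f3:
            self.proj = Sequential([
                Conv2D(cin, f3, 1, rng=rng, name=f"{name}.proj"),
                BatchNorm2D(f3, name=f"{name}.proj_bn"),
            ])
        self.relu = ReLU()
        self.cout = f3

    def children(self):
        out = [self.main]
        if self.proj is not None:
            out.append(self.proj)
        return out + [self.relu]

    def params(self):
        ps = self.main.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, training=False):
        main = self.main.forward(x, training)
        skip = self.proj.forward(x, training) if self.proj is not None else x
        return self.relu.forward(main + skip, training)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        dmain = self.main.backward(dy)
        dskip = self.proj.backward(dy) if self.proj is not None else dy
        return dmain + dskip


class ConvBlock(Layer):
    """Strided residual block of four 1x1 convolutions, pre-conv batch norm.

    Main path: BN -> ReLU -> 1x1(F1, stride s) -> BN -> ReLU -> 1x1(F2)
    -> BN -> ReLU -> 1x1(F3); shortcut: 1x1(F3, stride s) without batch
    norm. The stride is applied in the first conv and the shortcut.
    """

    def __init__(self, cin: int, filters: tuple[int, int, int], stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "convblock"):
        f1, f2, f3 = filters
        rng = rng if rng is not None else np.random.default_rng(0)
        self.main = Sequential([
            BatchNorm2D(cin, name=f"{name}.bn0"),
            ReLU(),
            Conv2D(cin, f1, 1, stride=stride, rng=rng, name=f"{name}.conv1"),
            BatchNorm2D(f1, name=f"{name}.bn1"),
            ReLU(),
            Conv2D(f1, f2, 1, rng=rng, name=f"{name}.conv2"),
            BatchNorm2D(f2, name=f"{name}.bn2"),
            ReLU(),
            Conv2D(f2, f3, 1, rng=rng, name=f"{name}.conv3"),
        ])
        self.shortcut = Conv2D(cin, f3, 1, stride=stride, rng=rng, name=f"{name}.shortcut")
        self.relu = ReLU()
        self.cout = f3

    def children(self):
        return [self.main, self.shortcut, self.relu]

    def params(self):
        return self.main.params() + self.shortcut.params()

    def forward(self, x, training=False):
        main = self.main.forward(x, training)
        skip = self.shortcut.forward(x, training)
        return self.relu.forward(main + skip, training)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        return self.main.backward(dy) + self.shortcut.backward(dy)


class InceptionBlock(Layer):
    """Four parallel branches concatenated channel-wise; ReLU only, no BN.

    Branches: 1x1(F1) | 1x1(F2) -> 3x3(F3) | 1x1(F4) -> 5x5(F5) |
    3x3 max-pool -> 1x1(F6).
    """

    def __init__(self, cin: int, filters: tuple[int, int, int, int, int, int],
                 rng: np.random.Generator | None = None, name: str = "inception"):
        f1, f2, f3, f4, f5, f6 = filters
        rng = rng if rng is not None else np.random.default_rng(0)
        self.branches = [
            Sequential([Conv2D(cin, f1, 1, rng=rng, name=f"{name}.b1"), ReLU()]),
            Sequential([
                Conv2D(cin, f2, 1, rng=rng, name=f"{name}.b2a"), ReLU(),
                Conv2D(f2, f3, 3, rng=rng, name=f"{name}.b2b"), ReLU(),
            ]),
            Sequential([
                Conv2D(cin, f4, 1, rng=rng, name=f"{name}.b3a"), ReLU(),
                Conv2D(f4, f5, 5, rng=rng, name=f"{name}.b3b"), ReLU(),
            ]),
            Sequential([
                MaxPool2D(3, 1, "same"),
                Conv2D(cin, f6, 1, rng=rng, name=f"{name}.b4"), ReLU(),
            ]),
        ]
        self._splits = (f1, f3, f5, f6)
        self.cout = f1 + f3 + f5 + f6

    def children(self):
        return list(self.branches)

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, training=False):
        outs = [b.forward(x, training) for b in self.branches]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        edges = np.cumsum((0,) + self._splits)
        dx = None
        for b, a, z in zip(self.branches, edges[:-1], edges[1:]):
            d = b.backward(dy[:, a:z])
            dx = d if dx is None else dx + d
        return dx
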