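"""Network assembly, parameter counting, and the softmax cross-entropy loss.

The default block configuration is frozen in ``resources/network_default.yaml``;
its exact layout (block order, filter assignments, batch-norm placement,
head) is pinned down by the published parameter totals of the full model:
553,794 parameters, of which 549,890 are trainable and 3,904 are the
batch-normalization running statistics.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from tumorseg.core_io import ValidationError
from tumorseg.nn.layers import (
    AvgPool2D,
    BatchNorm2D,
    Conv2D,
    ConvBlock,
    Dense,
    Flatten,
    IdentityBlock,
    InceptionBlock,
    Layer,
    MaxPool2D,
    ReLU,
    Sequential,
)

__all__ = ["BlockSpec", "NetworkSpec", "Network", "build_network", "count_parameters"]


@dataclass(frozen=True)
class BlockSpec:
    kind: str  # identity | convolution | inception
    filters: tuple[int, ...]
    stride: int = 1

    def __post_init__(self) -> None:
        expected = {"identity": 3, "convolution": 3, "inception": 6}
        if self.kind not in expected:
            raise ValidationError(f"unknown block kind {self.kind!r}")
        if len(self.filters) != expected[self.kind]:
            raise ValidationError(
                f"{self.kind} block needs {expected[self.kind]} filter counts, "
                f"got {self.filters}"
            )
        if any(f < 1 for f in self.filters):
            raise ValidationError("filter counts must be positive")
        if self.kind == "convolution" and self.stride not in (1, 2):
            raise ValidationError("convolution block stride must be 1 or 2")


@dataclass(frozen=True)
class NetworkSpec:
    """Input shape, stem, ordered blocks, and head of the classifier."""

    input_shape: tuple[int, int, int] = (256, 256, 1)
    stem_filters: int = 32
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_pool_kernel: int = 3
    stem_pool_stride: int = 2
    blocks: tuple[BlockSpec, ...] = ()
    head_pool_kernel: int = 5
    head_pool_stride: int = 3
    head_conv_filters: int = 64
    classes: int = 2

    @classmethod
    def default(cls) -> "NetworkSpec":
        """The frozen full-size configuration (see resources/network_default.yaml)."""
        text = (
            importlib.resources.files("tumorseg.resources")
            .joinpath("network_default.yaml")
            .read_text()
        )
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        blocks = tuple(
            BlockSpec(kind=b["kind"], filters=tuple(b["filters"]), stride=b.get("stride", 1))
            for b in d["blocks"]
        )
        stem = d.get("stem", {})
        head = d.get("head", {})
        return cls(
            input_shape=tuple(d.get("input", (256, 256, 1))),
            stem_filters=stem.get("filters", 32),
            stem_kernel=stem.get("kernel", 7),
            stem_stride=stem.get("stride", 2),
            stem_pool_kernel=stem.get("pool_kernel", 3),
            stem_pool_stride=stem.get("pool_stride", 2),
            blocks=blocks,
            head_pool_kernel=head.get("pool_kernel", 5),
            head_pool_stride=head.get("pool_stride", 3),
            head_conv_filters=head.get("conv_filters", 64),
            classes=head.get("classes", 2),
        )

    def scaled(self, width_scale: float, input_shape=None) -> "NetworkSpec":
        """Reduced-filter variant: every filter count scaled (minimum 1)."""

        def s(f: int) -> int:
            return max(1, int(round(f * width_scale)))

        blocks = tuple(
            BlockSpec(kind=b.kind, filters=tuple(s(f) for f in b.filters), stride=b.stride)
            for b in self.blocks
        )
        return NetworkSpec(
            input_shape=tuple(input_shape) if input_shape is not None else self.input_shape,
            stem_filters=s(self.stem_filters),
            stem_kernel=self.stem_kernel,
            stem_stride=self.stem_stride,
            stem_pool_kernel=self.stem_pool_kernel,
            stem_pool_stride=self.stem_pool_stride,
            blocks=blocks,
            head_pool_kernel=self.head_pool_kernel,
            head_pool_stride=self.head_pool_stride,
            head_conv_filters=s(self.head_conv_filters),
            classes=self.classes,
        )


def _ceil_div(n: int, s: int) -> int:
    return -(-n // s)


class Network:
    """A built model: ordered layers ending in logits over the classes."""

    def __init__(self, spec: NetworkSpec, body: Sequential):
        self.spec = spec
        self.body = body

    def params(self):
        return self.body.params()

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.body.forward(x, training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities via softmax over the logits."""
        z = self.logits(x, training)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def calibrate_batchnorm(self, x: np.ndarray, batch_size: int = 64) -> None:
        """Recompute batch-norm statistics with a stats-collection pass.

        Short training runs leave the exponential running averages lagging
        the final weights; this replaces them with plain averages of the
        batch statistics under the trained weights.
        """
        bns = [l for l in self.body.iter_layers() if isinstance(l, BatchNorm2D)]
        if not bns:
            return
        for bn in bns:
            bn.start_calibration()
        for i in range(0, x.shape[0], batch_size):
            self.body.forward(x[i : i + batch_size], training=True)
        for bn in bns:
            bn.finish_calibration()

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean cross-entropy over the batch; backpropagates to all params."""
        probs = self.forward(x, training=True)
        n = x.shape[0]
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
        dz = probs.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
        self.body.backward(dz.astype(np.float32))
        return loss, probs


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> Network:
    """Assemble the classifier from a :class:`NetworkSpec`.

    Weights are He-initialized from a generator seeded with ``seed``. The
    flatten size of the final dense layer is derived from the spec's spatial
    arithmetic, so any input size compatible with the stride chain works.
    """
    spec = spec if spec is not None else NetworkSpec.default()
    rng = np.random.default_rng(seed)
    h, w, cin = spec.input_shape

    layers: list[Layer] = [
        Conv2D(cin, spec.stem_filters, spec.stem_kernel, stride=spec.stem_stride,
               padding="same", rng=rng, name="stem.conv"),
        BatchNorm2D(spec.stem_filters, name="stem.bn"),
        ReLU(),
        MaxPool2D(spec.stem_pool_kernel, spec.stem_pool_stride, "same"),
    ]
    hh = _ceil_div(h, spec.stem_stride)
    ww = _ceil_div(w, spec.stem_stride)
    hh = _ceil_div(hh, spec.stem_pool_stride)
    ww = _ceil_div(ww, spec.stem_pool_stride)

    channels = spec.stem_filters
    for i, b in enumerate(spec.blocks):
        name = f"{b.kind}{i}"
        if b.kind == "identity":
            block = IdentityBlock(channels, b.filters, rng=rng, name=name)  # type: ignore[arg-type]
        elif b.kind == "convolution":
            block = ConvBlock(channels, b.filters, stride=b.stride, rng=rng, name=name)  # type: ignore[arg-type]
            hh = _ceil_div(hh, b.stride)
            ww = _ceil_div(ww, b.stride)
        else:
            block = InceptionBlock(channels, b.filters, rng=rng, name=name)  # type: ignore[arg-type]
        layers.append(block)
        channels = block.cout

    hh = (hh - spec.head_pool_kernel) // spec.head_pool_stride + 1
    ww = (ww - spec.head_pool_kernel) // spec.head_pool_stride + 1
    if hh < 1 or ww < 1:
        raise ValidationError(
            f"input {spec.input_shape} too small for the head pooling "
            f"({spec.head_pool_kernel}x{spec.head_pool_kernel} stride {spec.head_pool_stride})"
        )
    layers += [
        AvgPool2D(spec.head_pool_kernel, spec.head_pool_stride, "valid"),
        Conv2D(channels, spec.head_conv_filters, 1, rng=rng, name="head.conv"),
        ReLU(),
        Flatten(),
        Dense(spec.head_conv_filters * hh * ww, spec.classes, rng=rng, name="head.fc"),
    ]
    return Network(spec, Sequential(layers))


def count_parameters(model: Network | Layer) -> tuple[int, int]:
    """Exact (trainable, non_trainable) parameter counts."""
    trainable = 0
    non_trainable = 0
    for p in model.params():
        if p.trainable:
            trainable += p.size
        else:
            non_trainable += p.size
    return trainable, non_trainable
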