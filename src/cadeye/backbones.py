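"""Frozen convolutional feature extractors and global average pooling.

Two backbone families are provided, mirroring the characteristic building
blocks of the mobile/efficient CNN literature:

- ``mobilenet_v2_like`` — inverted residual blocks (1x1 expansion, depthwise
  3x3, linear 1x1 projection, additive skip when shape-preserving), ReLU6;
- ``efficientnet_b0_like`` — MBConv blocks (expansion, depthwise, a
  squeeze-and-excitation gate, linear projection, skip), swish activation.

Each family comes at two scales. ``tiny`` is a 3-stage reduced network that
runs fast on a CPU and is the scale the test suite and the synthetic-data
experiments use. ``full`` builds the family's canonical stage layout;
pretrained zoo weights cannot be fetched in an offline install, so ``full``
warns and falls back to seeded random initialization rather than failing
silently.

Backbones are frozen by construction: nothing in the package ever writes to
their parameters after :func:`build_backbone` returns, and :func:`checksum`
lets callers assert bit-identity across training runs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError
from .nn import conv2d, depthwise_conv2d, he_init, relu6, sigmoid, swish

__all__ = ["Backbone", "build_backbone", "extract", "gap", "checksum",
           "save_backbone", "load_backbone"]


# ----------------------------------------------------------------------------
# layer objects (forward-only; backbones are never trained)
# ----------------------------------------------------------------------------

_ACTS = {"relu6": relu6, "swish": swish, "linear": lambda x: x}


class ConvLayer:
    def __init__(self, rng, k, cin, cout, stride=1, activation="linear"):
        self.w = he_init(rng, (k, k, cin, cout), fan_in=k * k * cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.stride = stride
        self.activation = activation

    def forward(self, x):
        return _ACTS[self.activation](conv2d(x, self.w, self.b, stride=self.stride))

    def params(self):
        return [self.w, self.b]


class DepthwiseLayer:
    def __init__(self, rng, k, c, stride=1, activation="linear"):
        self.w = he_init(rng, (k, k, c), fan_in=k * k)
        self.b = np.zeros(c, dtype=np.float32)
        self.stride = stride
        self.activation = activation

    def forward(self, x):
        return _ACTS[self.activation](depthwise_conv2d(x, self.w, self.b, stride=self.stride))

    def params(self):
        return [self.w, self.b]


class SqueezeExcite:
    """Channel gate: global squeeze -> bottleneck ReLU -> sigmoid scale."""

    def __init__(self, rng, c, ratio=0.25):
        hidden = max(int(c * ratio), 1)
        self.w1 = he_init(rng, (c, hidden), fan_in=c)
        self.b1 = np.zeros(hidden, dtype=np.float32)
        self.w2 = he_init(rng, (hidden, c), fan_in=hidden)
        self.b2 = np.zeros(c, dtype=np.float32)

    def gate(self, x):
        s = x.mean(axis=(1, 2))                     # squeeze
        z = np.maximum(s @ self.w1 + self.b1, 0.0)  # excite
        return sigmoid(z @ self.w2 + self.b2)

    def forward(self, x):
        return x * self.gate(x)[:, None, None, :]

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]


class InvertedResidual:
    """MobileNetV2-style block: expand 1x1 -> depthwise 3x3 -> project 1x1."""

    def __init__(self, rng, cin, cout, stride, expand=4, activation="relu6"):
        ce = cin * expand
        self.expand = ConvLayer(rng, 1, cin, ce, activation=activation)
        self.depthwise = DepthwiseLayer(rng, 3, ce, stride=stride, activation=activation)
        self.project = ConvLayer(rng, 1, ce, cout, activation="linear")
        self.use_skip = stride == 1 and cin == cout

    def forward(self, x):
        y = self.project.forward(self.depthwise.forward(self.expand.forward(x)))
        return x + y if self.use_skip else y

    def params(self):
        return self.expand.params() + self.depthwise.params() + self.project.params()


class MBConv:
    """EfficientNet-style block: expansion, depthwise, SE gate, projection."""

    def __init__(self, rng, cin, cout, stride, expand=4, se_ratio=0.25):
        ce = cin * expand
        self.expand = ConvLayer(rng, 1, cin, ce, activation="swish")
        self.depthwise = DepthwiseLayer(rng, 3, ce, stride=stride, activation="swish")
        self.se = SqueezeExcite(rng, ce, ratio=se_ratio)
        self.project = ConvLayer(rng, 1, ce, cout, activation="linear")
        self.use_skip = stride == 1 and cin == cout

    def forward(self, x):
        y = self.se.forward(self.depthwise.forward(self.expand.forward(x)))
        y = self.project.forward(y)
        return x + y if self.use_skip else y

    def params(self):
        return (self.expand.params() + self.depthwise.params()
                + self.se.params() + self.project.params())


@dataclass
class Backbone:
    family: str
    scale: str
    layers: list = field(default_factory=list)
    output_channels: int = 0
    frozen: bool = True
    seed: int = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


_FAMILIES = ("mobilenet_v2_like", "efficientnet_b0_like")
_SCALES = ("tiny", "full")

# canonical (expand, cout, n_repeat, stride) stage tables for the full scale
_MOBILENET_V2_STAGES = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
                        (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1)]
_EFFICIENTNET_B0_STAGES = [(1, 16, 1, 1), (6, 24, 2, 2), (6, 40, 2, 2), (6, 80, 3, 2),
                           (6, 112, 3, 1), (6, 192, 4, 2), (6, 320, 1, 1)]


def build_backbone(family: str, scale: str = "tiny", seed: int = 0) -> Backbone:
    """Construct a frozen feature extractor, seeded and deterministic.

    ``tiny`` builds a 3-stage reduced network of the family's characteristic
    blocks; ``full`` builds the canonical stage layout but — with no reachable
    pretrained weight zoo — warns and initializes randomly from the seed.
    """
    if family not in _FAMILIES:
        raise ParameterError(f"unknown backbone family {family!r}; expected {_FAMILIES}")
    if scale not in _SCALES:
        raise ParameterError(f"unknown backbone scale {scale!r}; expected {_SCALES}")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, _FAMILIES.index(family), _SCALES.index(scale)]))
    layers: list = []
    if scale == "tiny":
        if family == "mobilenet_v2_like":
            layers.append(ConvLayer(rng, 3, 3, 8, stride=4, activation="relu6"))
            layers.append(InvertedResidual(rng, 8, 16, stride=2))
            layers.append(InvertedResidual(rng, 16, 24, stride=2))
            layers.append(InvertedResidual(rng, 24, 24, stride=1))
            cout = 24
        else:
            layers.append(ConvLayer(rng, 3, 3, 8, stride=4, activation="swish"))
            layers.append(MBConv(rng, 8, 16, stride=2))
            layers.append(MBConv(rng, 16, 24, stride=2))
            layers.append(MBConv(rng, 24, 32, stride=2))
            cout = 32
    else:
        warnings.warn(
            f"no pretrained weights are available for {family}/{scale}; "
            "initializing from the seed instead", stacklevel=2)
        stages = (_MOBILENET_V2_STAGES if family == "mobilenet_v2_like"
                  else _EFFICIENTNET_B0_STAGES)
        act = "relu6" if family == "mobilenet_v2_like" else "swish"
        block = InvertedResidual if family == "mobilenet_v2_like" else MBConv
        layers.append(ConvLayer(rng, 3, 3, 32, stride=2, activation=act))
        cin = 32
        for expand, c, n, s in stages:
            for i in range(n):
                layers.append(block(rng, cin, c, stride=s if i == 0 else 1,
                                    expand=expand))
                cin = c
        layers.append(ConvLayer(rng, 1, cin, 1280, activation=act))
        cout = 1280
    return Backbone(family=family, scale=scale, layers=layers,
                    output_channels=cout, frozen=True, seed=int(seed))


def extract(backbone: Backbone, batch: np.ndarray) -> np.ndarray:
    """Final-convolutional-stage activations for a normalized NHWC batch.

    No parameter is updated; the returned feature map has ``output_channels``
    channels. Inputs must be large enough to survive the backbone's strides.
    """
    x = np.asarray(batch, dtype=np.float32)
    if x.ndim != 4 or x.shape[3] != 3:
        raise ShapeError(f"expected an N x H x W x 3 batch, got {x.shape}")
    if min(x.shape[1], x.shape[2]) < 16:
        raise ShapeError("input spatial size must be at least 16 x 16")
    fmap = backbone.forward(x)
    if not np.all(np.isfinite(fmap)):
        raise ValueError("non-finite activations in feature map")
    return fmap


def gap(fmap: np.ndarray) -> np.ndarray:
    """Global average pooling: per-channel mean over both spatial axes."""
    fmap = np.asarray(fmap)
    if fmap.ndim != 4:
        raise ShapeError(f"expected a 4-axis feature map, got {fmap.shape}")
    return fmap.mean(axis=(1, 2))


def checksum(backbone: Backbone) -> str:
    """SHA-256 over all parameters; equality certifies the freeze contract."""
    h = hashlib.sha256()
    for p in backbone.params():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()


def save_backbone(backbone: Backbone, path) -> None:
    """Portable checkpoint: JSON header + npz weight archive at ``path``."""
    import io
    params = backbone.params()
    header = {
        "family": backbone.family,
        "scale": backbone.scale,
        "seed": backbone.seed,
        "output_channels": backbone.output_channels,
        "checksum": checksum(backbone),
        "n_arrays": len(params),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(header, fh, indent=2)
    np.savez(str(path) + ".npz", *params)


def load_backbone(path) -> Backbone:
    with open(str(path) + ".json") as fh:
        header = json.load(fh)
    bb = build_backbone(header["family"], header["scale"], header["seed"])
    archive = np.load(str(path) + ".npz")
    arrays = [archive[f"arr_{i}"] for i in range(header["n_arrays"])]
    for p, a in zip(bb.params(), arrays):
        p[...] = a
    if checksum(bb) != header["checksum"]:
        raise ValueError("checkpoint checksum mismatch")
    return bb
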