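"""Architecture builders with table-exact output-shape contracts.

Each builder produces a :class:`NetworkSpec`: an ordered list of layer
descriptors, the symbolic shape trace obtained by composing them over the
declared input shape, and — for the small 2D scoring networks and the crop
integration head — a runnable, trainable network.  The 3D feature
extractors (Alex3D, VGG16-3D, ResNet18-3D) are described and shape-checked
symbolically; their printed output sizes pin down the stride/padding choices
the builders encode, and any drift raises an error naming the offending
layer.

All scoring networks end in a single linear unit: the scalar log relative
hazard f(x; Θ).  In the two-task setting the same scalar is also read as a
cancer probability through a sigmoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "trace_shapes",
    "build_sim_net_ab",
    "build_sim_net_c",
    "build_alex3d",
    "build_vgg16_3d",
    "build_resnet18_3d",
    "CropIntegrationHead",
    "integrate_crops",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer: kind, kernel count/size, stride, padding or units."""

    kind: str  # conv | maxpool | avgpool_global | resblock | flatten | dense
    kernels: Optional[int] = None
    kernel_size: Optional[int] = None
    stride: int = 1
    padding: str = "same"  # conv: same/valid; pool: valid(floor)/same(ceil)
    units: Optional[int] = None
    name: str = ""


@dataclass
class NetworkSpec:
    """An architecture plus its composed shape trace and parameter count.

    ``network`` is a runnable :class:`minicox.nn.Sequential` when the
    architecture is small enough to train on a CPU; otherwise ``None`` and
    the spec serves as a checked structural description.
    """

    name: str
    input_shape: tuple
    layers: list
    trace: list  # [(layer name, output shape tuple)]
    network: Optional[nn.Sequential] = None

    @property
    def output_dim(self) -> int:
        shape = self.trace[-1][1]
        return int(np.prod(shape))

    def parameter_count(self) -> int:
        total = 0
        shape = self.input_shape
        for spec, (_, out_shape) in zip(self.layers, self.trace):
            c_in = shape[-1] if len(shape) > 1 else shape[0]
            if spec.kind == "conv":
                k = spec.kernel_size ** (len(shape) - 1)
                total += k * c_in * spec.kernels + spec.kernels
            elif spec.kind == "resblock":
                k = spec.kernel_size ** (len(shape) - 1)
                total += k * c_in * spec.kernels + spec.kernels
                total += k * spec.kernels * spec.kernels + spec.kernels
                if spec.stride != 1 or c_in != spec.kernels:
                    total += c_in * spec.kernels + spec.kernels  # projection
            elif spec.kind == "dense":
                total += int(np.prod(shape)) * spec.units + spec.units
            shape = out_shape
        return total

    def describe(self) -> str:
        lines = [f"{self.name}  input {self.input_shape}"]
        for spec, (label, shape) in zip(self.layers, self.trace):
            lines.append(f"  {label:<22} -> {'×'.join(map(str, shape))}")
        return "\n".join(lines)


class ShapeError(ValueError):
    """A layer's composed output shape disagrees with its table."""


def _conv_dim(d: int, k: int, s: int, padding: str) -> int:
    if padding == "same":
        return math.ceil(d / s)
    return (d - k) // s + 1


def trace_shapes(input_shape: Sequence[int], layers: Sequence[LayerSpec]) -> list:
    """Compose layer descriptors over an input shape, channels-last."""
    shape = tuple(input_shape)
    out = []
    for i, spec in enumerate(layers):
        label = spec.name or f"{spec.kind}_{i}"
        if spec.kind == "conv":
            spatial = [_conv_dim(d, spec.kernel_size, spec.stride, spec.padding)
                       for d in shape[:-1]]
            shape = (*spatial, spec.kernels)
        elif spec.kind == "maxpool":
            spatial = [_conv_dim(d, spec.kernel_size, spec.stride, spec.padding)
                       for d in shape[:-1]]
            shape = (*spatial, shape[-1])
        elif spec.kind == "resblock":
            spatial = [math.ceil(d / spec.stride) for d in shape[:-1]]
            shape = (*spatial, spec.kernels)
        elif spec.kind == "avgpool_global":
            shape = (shape[-1],)
        elif spec.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif spec.kind == "dense":
            if len(shape) != 1:
                raise ShapeError(f"{label}: dense layer needs a flat input")
            shape = (spec.units,)
        else:
            raise ValueError(f"unknown layer kind {spec.kind!r}")
        out.append((label, shape))
    return out


def _check_trace(name: str, trace: list, expected: dict) -> None:
    """``expected`` maps layer label -> shape tuple from the printed table."""
    got = dict(trace)
    for label, shape in expected.items():
        if got.get(label) != shape:
            raise ShapeError(
                f"{name}: layer {label!r} produces {got.get(label)}, "
                f"table requires {shape}"
            )


# ---------------------------------------------------------------------------
# simulation networks (runnable)
# ---------------------------------------------------------------------------

def _sim_trunk() -> list:
    return [
        LayerSpec("conv", kernels=32, kernel_size=5, padding="same", name="conv1"),
        LayerSpec("maxpool", kernel_size=2, stride=2, padding="valid", name="pool1"),
        LayerSpec("conv", kernels=64, kernel_size=5, padding="same", name="conv2"),
        LayerSpec("maxpool", kernel_size=2, stride=2, padding="valid", name="pool2"),
        LayerSpec("flatten", name="flatten"),
    ]


def _build_runnable(input_shape, layers, rng, dtype=np.float32) -> nn.Sequential:
    modules = []
    shape = tuple(input_shape)
    for spec in layers:
        if spec.kind == "conv":
            modules.append(
                nn.Conv2d(shape[-1], spec.kernels, spec.kernel_size, rng,
                          padding=spec.padding, dtype=dtype)
            )
            modules.append(nn.ReLU(slope=0.01))
            shape = (*[_conv_dim(d, spec.kernel_size, 1, spec.padding)
                       for d in shape[:-1]], spec.kernels)
        elif spec.kind == "maxpool":
            modules.append(nn.MaxPool2d())
            shape = (*[d // 2 for d in shape[:-1]], shape[-1])
        elif spec.kind == "flatten":
            modules.append(nn.Flatten())
            shape = (int(np.prod(shape)),)
        elif spec.kind == "dense":
            modules.append(nn.Dense(shape[0], spec.units, rng, dtype=dtype))
            if spec.units > 1:  # hidden layers get a rectifier, the score does not
                modules.append(nn.ReLU(slope=0.01))
            shape = (spec.units,)
    return nn.Sequential(modules)


def build_sim_net_ab(input_shape=(28, 28, 1), seed: int = 0,
                     dtype=np.float32) -> NetworkSpec:
    """The two-class simulation CNN: conv32 → pool → conv64 → pool →
    dense 1024 → 128 → 1."""
    if tuple(input_shape) != (28, 28, 1):
        raise ValueError(f"expected input 28×28×1, got {input_shape}")
    layers = _sim_trunk() + [
        LayerSpec("dense", units=1024, name="fc1"),
        LayerSpec("dense", units=128, name="fc2"),
        LayerSpec("dense", units=1, name="score"),
    ]
    trace = trace_shapes(input_shape, layers)
    _check_trace("sim_net_ab", trace, {
        "conv1": (28, 28, 32),
        "pool1": (14, 14, 32),
        "conv2": (14, 14, 64),
        "pool2": (7, 7, 64),
        "flatten": (3136,),
        "fc1": (1024,),
        "fc2": (128,),
        "score": (1,),
    })
    rng = np.random.default_rng(seed)
    net = _build_runnable(input_shape, layers, rng, dtype=dtype)
    return NetworkSpec("sim_net_ab", tuple(input_shape), layers, trace, net)


def build_sim_net_c(input_shape=(32, 32, 3), seed: int = 0,
                    dtype=np.float32) -> NetworkSpec:
    """The two-task simulation CNN: same conv trunk, dense 100 → 10 → 1.

    Its single output is used twice — raw as the log relative hazard and
    through a sigmoid as the cancer probability.
    """
    if tuple(input_shape) != (32, 32, 3):
        raise ValueError(f"expected input 32×32×3, got {input_shape}")
    layers = _sim_trunk() + [
        LayerSpec("dense", units=100, name="fc1"),
        LayerSpec("dense", units=10, name="fc2"),
        LayerSpec("dense", units=1, name="score"),
    ]
    trace = trace_shapes(input_shape, layers)
    _check_trace("sim_net_c", trace, {
        "conv1": (32, 32, 32),
        "pool2": (8, 8, 64),
        "flatten": (4096,),
        "fc1": (100,),
        "fc2": (10,),
        "score": (1,),
    })
    rng = np.random.default_rng(seed)
    net = _build_runnable(input_shape, layers, rng, dtype=dtype)
    return NetworkSpec("sim_net_c", tuple(input_shape), layers, trace, net)


# ---------------------------------------------------------------------------
# 3D feature extractors (structural specs, shape-checked against the tables)
# ---------------------------------------------------------------------------

def build_alex3d(input_shape=(96, 96, 96, 1)) -> NetworkSpec:
    """3D AlexNet-style extractor ending flatten(16384) → 4096 → 128.

    The printed sizes force the unstated geometry: a stride-2 same-padded
    first convolution (96→48), valid 3³ pools with stride 2 (48→23→11,
    9→4), one valid 3³ convolution (11→9) and same padding elsewhere.
    """
    if tuple(input_shape) != (96, 96, 96, 1):
        raise ValueError(f"expected input 96×96×96×1, got {input_shape}")
    layers = [
        LayerSpec("conv", kernels=96, kernel_size=3, stride=2, padding="same", name="conv1"),
        LayerSpec("maxpool", kernel_size=3, stride=2, padding="valid", name="pool1"),
        LayerSpec("conv", kernels=256, kernel_size=5, padding="same", name="conv2"),
        LayerSpec("maxpool", kernel_size=3, stride=2, padding="valid", name="pool2"),
        LayerSpec("conv", kernels=384, kernel_size=3, padding="valid", name="conv3"),
        LayerSpec("conv", kernels=256, kernel_size=3, padding="same", name="conv4"),
        LayerSpec("maxpool", kernel_size=3, stride=2, padding="valid", name="pool3"),
        LayerSpec("flatten", name="flatten"),
        LayerSpec("dense", units=4096, name="fc1"),
        LayerSpec("dense", units=128, name="feature"),
    ]
    trace = trace_shapes(input_shape, layers)
    _check_trace("alex3d", trace, {
        "conv1": (48, 48, 48, 96),
        "pool1": (23, 23, 23, 96),
        "conv2": (23, 23, 23, 256),
        "pool2": (11, 11, 11, 256),
        "conv3": (9, 9, 9, 384),
        "conv4": (9, 9, 9, 256),
        "pool3": (4, 4, 4, 256),
        "flatten": (16384,),
        "fc1": (4096,),
        "feature": (128,),
    })
    return NetworkSpec("alex3d", tuple(input_shape), layers, trace, None)


def build_vgg16_3d(input_shape=(96, 96, 96, 1)) -> NetworkSpec:
    """3D VGG16 extractor: 13 same-padded 3³ convolutions, five ceil-mode
    stride-2 pools, flatten(13824) → 4096 → 4096 → 128."""
    if tuple(input_shape) != (96, 96, 96, 1):
        raise ValueError(f"expected input 96×96×96×1, got {input_shape}")
    cfg = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
    layers: list[LayerSpec] = []
    for stage, (width, reps) in enumerate(cfg, start=1):
        for rep in range(1, reps + 1):
            layers.append(LayerSpec("conv", kernels=width, kernel_size=3,
                                    padding="same", name=f"conv{stage}_{rep}"))
        layers.append(LayerSpec("maxpool", kernel_size=3, stride=2,
                                padding="same", name=f"pool{stage}"))
    layers += [
        LayerSpec("flatten", name="flatten"),
        LayerSpec("dense", units=4096, name="fc1"),
        LayerSpec("dense", units=4096, name="fc2"),
        LayerSpec("dense", units=128, name="feature"),
    ]
    trace = trace_shapes(input_shape, layers)
    _check_trace("vgg16_3d", trace, {
        "pool1": (48, 48, 48, 64),
        "pool2": (24, 24, 24, 128),
        "pool3": (12, 12, 12, 256),
        "pool4": (6, 6, 6, 512),
        "pool5": (3, 3, 3, 512),
        "flatten": (13824,),
        "fc1": (4096,),
        "fc2": (4096,),
        "feature": (128,),
    })
    return NetworkSpec("vgg16_3d", tuple(input_shape), layers, trace, None)


def build_resnet18_3d(input_shape=(96, 96, 96, 1)) -> NetworkSpec:
    """3D ResNet-18: 7³ stride-2 stem, 3³ stride-2 pool, four two-block
    residual stages (64/128/256/512, downsampling in the first block of
    stages 2–4), global average pool, dense 128."""
    if tuple(input_shape) != (96, 96, 96, 1):
        raise ValueError(f"expected input 96×96×96×1, got {input_shape}")
    layers = [
        LayerSpec("conv", kernels=64, kernel_size=7, stride=2, padding="same", name="conv1"),
        LayerSpec("maxpool", kernel_size=3, stride=2, padding="same", name="pool1"),
    ]
    for stage, width in enumerate((64, 128, 256, 512), start=1):
        stride = 1 if stage == 1 else 2
        layers.append(LayerSpec("resblock", kernels=width, kernel_size=3,
                                stride=stride, name=f"res{stage}_1"))
        layers.append(LayerSpec("resblock", kernels=width, kernel_size=3,
                                stride=1, name=f"res{stage}_2"))
    layers += [
        LayerSpec("avgpool_global", name="avgpool"),
        LayerSpec("dense", units=128, name="feature"),
    ]
    trace = trace_shapes(input_shape, layers)
    _check_trace("resnet18_3d", trace, {
        "conv1": (48, 48, 48, 64),
        "pool1": (24, 24, 24, 64),
        "res1_2": (24, 24, 24, 64),
        "res2_2": (12, 12, 12, 128),
        "res3_2": (6, 6, 6, 256),
        "res4_2": (3, 3, 3, 512),
        "avgpool": (512,),
        "feature": (128,),
    })
    return NetworkSpec("resnet18_3d", tuple(input_shape), layers, trace, None)


# ---------------------------------------------------------------------------
# five-crop integration head
# ---------------------------------------------------------------------------

class CropIntegrationHead:
    """Combines five per-crop 128-D features into one hazard score.

    A shared dense layer (128 → 32) is applied to each crop, the maximum of
    each crop's 32 activations is taken, the five maxima are concatenated,
    and a final dense layer (5 → 1) emits f.  Sharing the first layer makes
    the five maxima permute with the crops.
    """

    N_CROPS = 5

    def __init__(self, seed: int = 0, n_features: int = 128, hidden: int = 32) -> None:
        rng = np.random.default_rng(seed)
        self.shared = nn.Dense(n_features, hidden, rng)
        self.final = nn.Dense(self.N_CROPS, 1, rng)
        self.n_features = n_features

    def forward(self, features: np.ndarray) -> float:
        features = np.asarray(features, dtype=float)
        if features.shape != (self.N_CROPS, self.n_features):
            raise ValueError(
                f"expected {self.N_CROPS} feature vectors of length "
                f"{self.n_features}, got shape {features.shape}"
            )
        hidden = self.shared.forward(features)        # (5, 32)
        self._argmax = hidden.argmax(axis=1)
        maxima = hidden.max(axis=1)                   # (5,)
        self._hidden_shape = hidden.shape
        out = self.final.forward(maxima[None, :])     # (1, 1)
        return float(out[0, 0])

    def backward(self, grad_out: float) -> np.ndarray:
        g = self.final.backward(np.array([[grad_out]]))[0]  # (5,)
        dhidden = np.zeros(self._hidden_shape)
        dhidden[np.arange(self.N_CROPS), self._argmax] = g
        return self.shared.backward(dhidden)

    def parameters(self):
        return self.shared.parameters() + self.final.parameters()


def integrate_crops(features, head: Optional[CropIntegrationHead] = None) -> float:
    """Score a stack of five 128-D crop features with an integration head."""
    if head is None:
        head = CropIntegrationHead()
    return head.forward(np.asarray(features, dtype=float))
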