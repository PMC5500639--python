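"""Architecture specifications, shape algebra and the network container.

An :class:`ArchitectureSpec` is the in-code form of one architecture-table
column: an ordered list of layer specifications plus the nominal input size
and task kind.  Shape validation is total — every mismatch is caught at
construction, before any training step.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from ..augment import crop_size
from ..errors import ConfigurationError, ShapeError
from .layers import Conv2D, Dense, Dropout, Layer, MaxPool2D, xavier_init
from .losses import softmax

LAYER_KINDS = ("conv", "pool", "fully_connected", "dropout", "output")
ACTIVATIONS = ("tanh", "relu", "none")


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    kernel: Optional[tuple[int, int]] = None
    filters: Optional[int] = None
    stride: int = 1
    units: Optional[int] = None
    drop_prob: float = 0.0
    activation: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ConfigurationError(f"unknown layer kind {self.kind!r}; expected one of {LAYER_KINDS}")
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.kind in ("conv", "pool"):
            if self.kernel is None or self.kernel[0] < 1 or self.kernel[1] < 1:
                raise ConfigurationError(f"{self.kind} layer needs a positive kernel, got {self.kernel}")
            if self.stride < 1:
                raise ConfigurationError(f"{self.kind} stride must be >= 1")
        if self.kind == "conv" and (self.filters is None or self.filters < 1):
            raise ConfigurationError("conv layer needs filters >= 1")
        if self.kind in ("fully_connected", "output") and (self.units is None or self.units < 1):
            raise ConfigurationError(f"{self.kind} layer needs units >= 1")
        if self.kind == "output" and self.activation != "none":
            raise ConfigurationError("output layers carry no activation")
        if self.kind == "dropout" and not 0.0 <= self.drop_prob < 1.0:
            raise ConfigurationError("dropout probability must be in [0, 1)")


def conv(kernel: int | tuple[int, int], filters: int, activation: str = "tanh") -> LayerSpec:
    k = (kernel, kernel) if isinstance(kernel, int) else tuple(kernel)
    return LayerSpec(kind="conv", kernel=k, filters=filters, stride=1, activation=activation)


def pool(kernel: int | tuple[int, int] = 3, stride: int = 2) -> LayerSpec:
    k = (kernel, kernel) if isinstance(kernel, int) else tuple(kernel)
    return LayerSpec(kind="pool", kernel=k, stride=stride)


def fully_connected(units: int, activation: str = "tanh") -> LayerSpec:
    return LayerSpec(kind="fully_connected", units=units, activation=activation)


def dropout(drop_prob: float) -> LayerSpec:
    return LayerSpec(kind="dropout", drop_prob=drop_prob)


def output(units: int) -> LayerSpec:
    return LayerSpec(kind="output", units=units, activation="none")


def output_shape(layer: LayerSpec, in_shape: tuple[int, ...]) -> tuple[int, ...]:
    """Shape algebra for one layer.

    Same-padded stride-1 convolution maps (n, m, c) to (n, m, filters);
    same-padded pooling with stride s maps n to ceil(n/s); fully connected
    layers flatten; dropout is the identity.
    """
    if layer.kind in ("conv", "pool"):
        if len(in_shape) != 3:
            raise ShapeError(f"{layer.kind} layer needs an (n, m, c) volume, got shape {in_shape}")
        n, m, c = in_shape
        s = layer.stride
        n2, m2 = math.ceil(n / s), math.ceil(m / s)
        if n2 < 1 or m2 < 1:
            raise ShapeError(f"{layer.kind} layer collapses {in_shape} to an empty volume")
        return (n2, m2, layer.filters if layer.kind == "conv" else c)
    if layer.kind in ("fully_connected", "output"):
        dim = int(np.prod(in_shape))
        if dim < 1:
            raise ShapeError(f"{layer.kind} layer fed an empty volume {in_shape}")
        return (layer.units,)
    return tuple(in_shape)  # dropout


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer stack plus input geometry and task kind.

    ``input_size`` is the nominal (resize) size; training crops remove a
    linear ``crop_fraction`` per side, and test-time center crops produce
    the same spatial size, so the network is instantiated at the crop size.
    """

    name: str
    input_size: tuple[int, int]
    layers: tuple[LayerSpec, ...]
    task: str
    outputs: int
    crop_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if not self.layers or self.layers[-1].kind != "output":
            raise ConfigurationError("architecture must end with an output layer")
        if self.layers[-1].units != self.outputs:
            raise ConfigurationError(
                f"output layer has {self.layers[-1].units} units but spec declares {self.outputs}"
            )
        object.__setattr__(self, "layers", tuple(self.layers))
        validate_spec(self)

    @property
    def train_input_size(self) -> tuple[int, int]:
        n, m = self.input_size
        return (crop_size(n, self.crop_fraction), crop_size(m, self.crop_fraction))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        d["input_size"] = tuple(d["input_size"])
        d["layers"] = tuple(
            LayerSpec(**{**ls, "kernel": tuple(ls["kernel"]) if ls["kernel"] else None})
            for ls in d["layers"]
        )
        return cls(**d)


def validate_spec(spec: ArchitectureSpec) -> tuple[int, ...]:
    """Run the shape algebra end to end; returns the final output shape."""
    shape: tuple[int, ...] = (*spec.train_input_size, 3)
    for i, layer in enumerate(spec.layers):
        try:
            shape = output_shape(layer, shape)
        except ShapeError as exc:
            raise ShapeError(f"{spec.name}: layer {i} ({layer.kind}): {exc}") from exc
    if shape != (spec.outputs,):
        raise ShapeError(f"{spec.name}: final shape {shape} != declared outputs ({spec.outputs},)")
    return shape


def count_parameters(spec: ArchitectureSpec) -> int:
    """Closed-form trainable-parameter count.

    conv: kh*kw*c_in*filters + filters; fully connected (and output):
    in_dim*units + units; pool and dropout contribute nothing.
    """
    shape: tuple[int, ...] = (*spec.train_input_size, 3)
    total = 0
    for layer in spec.layers:
        if layer.kind == "conv":
            kh, kw = layer.kernel
            total += kh * kw * shape[2] * layer.filters + layer.filters
        elif layer.kind in ("fully_connected", "output"):
            total += int(np.prod(shape)) * layer.units + layer.units
        shape = output_shape(layer, shape)
    return total


class Network:
    """Instantiated parameters for one :class:`ArchitectureSpec`.

    ``forward`` in evaluation mode returns log-normalized class
    probabilities for classification tasks (rows sum to 1) and raw real
    outputs for regression; dropout is active only when ``training=True``.
    ``backward`` expects the gradient with respect to the output layer's
    pre-activations (for classification: probabilities minus one-hot).
    """

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers: list[Layer] = []
        shape: tuple[int, ...] = (*spec.train_input_size, 3)
        for ls in spec.layers:
            if ls.kind == "conv":
                self.layers.append(Conv2D(ls.kernel, shape[2], ls.filters, ls.activation, rng))
            elif ls.kind == "pool":
                self.layers.append(MaxPool2D(ls.kernel, ls.stride))
            elif ls.kind in ("fully_connected", "output"):
                self.layers.append(Dense(int(np.prod(shape)), ls.units, ls.activation, rng))
            elif ls.kind == "dropout":
                self.layers.append(Dropout(ls.drop_prob))
            shape = output_shape(ls, shape)

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        expected = (*self.spec.train_input_size, 3)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ShapeError(
                f"{self.spec.name}: expected batch of shape (n, {expected[0]}, {expected[1]}, 3), "
                f"got {x.shape}"
            )
        h = x
        for layer in self.layers:
            h = layer.forward(h, training, rng)
        if self.spec.task == "classification":
            return softmax(h)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = np.asarray(dout, dtype=np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [pg for layer in self.layers for pg in layer.params()]

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    @property
    def parameter_count(self) -> int:
        return sum(int(p.size) for p, _ in self.params())

    def weights(self) -> dict[str, np.ndarray]:
        """Named parameter arrays, in layer order."""
        named: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, (p, _) in enumerate(layer.params()):
                suffix = "W" if j == 0 else "b"
                named[f"layer{i:02d}_{suffix}"] = p
        return named

    def first_conv_weights(self) -> np.ndarray:
        for layer in self.layers:
            if isinstance(layer, Conv2D):
                return layer.W
        raise ConfigurationError(f"{self.spec.name} has no convolutional layer")

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: spec JSON plus named weight arrays (npz)."""
        arrays = {k: v for k, v in self.weights().items()}
        arrays["__spec__"] = np.frombuffer(self.spec.to_json().encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        with np.load(path) as data:
            spec = ArchitectureSpec.from_json(bytes(data["__spec__"]).decode())
            net = cls(spec, np.random.default_rng(0))
            named = net.weights()
            for key, arr in named.items():
                arr[...] = data[key]
        return net


def load_checkpoint(path: str | Path) -> Network:
    return Network.load(path)
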