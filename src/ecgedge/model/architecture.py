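"""CNN architecture spec, training configuration, and weight containers.

The network is four convolution blocks (3x3 kernels, 64 filters, ReLU,
same-padding, 2x2 max-pool) followed by flatten, two ReLU dense layers,
dropout, and a 2-class softmax head. Input spatial dims must be divisible
by 2^4 so the four poolings produce integer feature maps. Class order is
fixed: index 0 = non-AF, index 1 = AF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_ORDER = ("nonAF", "AF")


class SpecError(ValueError):
    """Invalid architecture specification."""


@dataclass
class CnnSpec:
    input_height: int = 128
    input_width: int = 96
    n_blocks: int = 4
    filters: int = 64
    kernel_size: int = 3
    dense1: int = 128
    dense2: int = 64
    dropout_rate: float = 0.5
    n_classes: int = 2

    def validate(self) -> None:
        div = 2**self.n_blocks
        if self.input_height % div or self.input_width % div:
            raise SpecError(
                f"input dims {self.input_height}x{self.input_width} not divisible by {div}"
            )
        if self.n_classes != 2:
            raise SpecError("the classifier head is 2-class")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise SpecError("dropout rate must be in [0, 1)")

    @property
    def feature_shape(self) -> tuple[int, int, int]:
        div = 2**self.n_blocks
        return (self.input_height // div, self.input_width // div, self.filters)

    @property
    def flatten_size(self) -> int:
        h, w, c = self.feature_shape
        return h * w * c


def parameter_count(spec: CnnSpec) -> int:
    """Closed-form trainable parameter count from the layer shapes."""
    spec.validate()
    k2 = spec.kernel_size**2
    total = 0
    cin = 1
    for _ in range(spec.n_blocks):
        total += (k2 * cin) * spec.filters + spec.filters
        cin = spec.filters
    total += spec.flatten_size * spec.dense1 + spec.dense1
    total += spec.dense1 * spec.dense2 + spec.dense2
    total += spec.dense2 * spec.n_classes + spec.n_classes
    return total


@dataclass
class TrainConfig:
    """Training hyperparameters. Defaults follow the published recipe:
    batch 64, 150 epochs, Adam at 1e-4 initial learning rate with a
    per-update decay of 1e-6 (legacy semantics: lr / (1 + decay * step)),
    categorical cross-entropy loss."""

    batch_size: int = 64
    epochs: int = 150
    learning_rate: float = 1e-4
    lr_decay: float = 1e-6
    seed: int = 0
    checkpoint: str = "val_auc"  # keep weights of the best-validation epoch
    # NumPy compute is bit-deterministic for a fixed seed and platform; the
    # flag is kept so callers can demand it explicitly.
    deterministic: bool = True

    def validate(self) -> None:
        if self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("batch_size must be positive, epochs non-negative")
        if self.learning_rate <= 0 or self.lr_decay < 0:
            raise ValueError("learning_rate must be > 0 and lr_decay >= 0")


@dataclass
class ModelBundle:
    """Architecture + per-layer weights + training metadata.

    Weight keys: ``conv{i}_W`` (kh, kw, cin, cout) / ``conv{i}_b`` for
    i = 1..n_blocks, then ``dense1_W`` (in, out), ``dense1_b``,
    ``dense2_W``, ``dense2_b``, ``out_W``, ``out_b``.
    """

    spec: CnnSpec
    weights: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.weights.values()))


def _expected_shapes(spec: CnnSpec) -> dict[str, tuple[int, ...]]:
    shapes: dict[str, tuple[int, ...]] = {}
    cin = 1
    for i in range(1, spec.n_blocks + 1):
        shapes[f"conv{i}_W"] = (spec.kernel_size, spec.kernel_size, cin, spec.filters)
        shapes[f"conv{i}_b"] = (spec.filters,)
        cin = spec.filters
    shapes["dense1_W"] = (spec.flatten_size, spec.dense1)
    shapes["dense1_b"] = (spec.dense1,)
    shapes["dense2_W"] = (spec.dense1, spec.dense2)
    shapes["dense2_b"] = (spec.dense2,)
    shapes["out_W"] = (spec.dense2, spec.n_classes)
    shapes["out_b"] = (spec.n_classes,)
    return shapes


def build_model(spec: CnnSpec, seed: int = 0) -> ModelBundle:
    """Untrained bundle with He-normal weights and zero biases (seeded)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    for name, shape in _expected_shapes(spec).items():
        if name.endswith("_b"):
            weights[name] = np.zeros(shape, dtype=np.float32)
        else:
            fan_in = int(np.prod(shape[:-1]))
            std = np.sqrt(2.0 / fan_in)
            weights[name] = rng.normal(0.0, std, size=shape).astype(np.float32)
    return ModelBundle(spec=spec, weights=weights, metadata={"trained_epochs": 0})


def validate_weights(spec: CnnSpec, weights: dict[str, np.ndarray]) -> None:
    expected = _expected_shapes(spec)
    missing = set(expected) - set(weights)
    if missing:
        raise SpecError(f"missing weight arrays: {sorted(missing)}")
    for name, shape in expected.items():
        if tuple(weights[name].shape) != shape:
            raise SpecError(
                f"weight {name} shaped {weights[name].shape}, expected {shape}"
            )
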