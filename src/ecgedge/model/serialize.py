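"""Round-trippable JSON model document for edge deployment.

The document is self-describing: it records the layer sequence, weight
shapes, the kernel ordering convention (HWIO), the flatten order (HWC,
row-major), and the class order, so an independent engine can reproduce
the forward pass exactly. Weights are float32; JSON decimal text preserves
them losslessly (float32 -> double -> decimal round-trips exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .architecture import CLASS_ORDER, CnnSpec, ModelBundle, validate_weights

FORMAT_NAME = "ecgedge-cnn"
FORMAT_VERSION = 1


class FormatError(ValueError):
    """Malformed or inconsistent model document."""


def export_json(bundle: ModelBundle) -> dict:
    """Serialize a bundle into a plain JSON-compatible dict."""
    spec = bundle.spec
    spec.validate()
    validate_weights(spec, bundle.weights)
    w = bundle.weights
    layers: list[dict] = []
    for i in range(1, spec.n_blocks + 1):
        layers.append(
            {
                "type": "conv2d",
                "name": f"conv{i}",
                "kernel_order": "HWIO",
                "padding": "same",
                "activation": "relu",
                "kernel_shape": list(w[f"conv{i}_W"].shape),
                "kernel": w[f"conv{i}_W"].astype(float).tolist(),
                "bias": w[f"conv{i}_b"].astype(float).tolist(),
            }
        )
        layers.append({"type": "maxpool2d", "name": f"pool{i}", "size": 2, "stride": 2})
    layers.append({"type": "flatten", "name": "flatten", "order": "HWC"})
    for name, act in (("dense1", "relu"), ("dense2", "relu")):
        layers.append(
            {
                "type": "dense",
                "name": name,
                "activation": act,
                "weight_shape": list(w[f"{name}_W"].shape),
                "weights": w[f"{name}_W"].astype(float).tolist(),
                "bias": w[f"{name}_b"].astype(float).tolist(),
            }
        )
    layers.append({"type": "dropout", "name": "dropout", "rate": spec.dropout_rate})
    layers.append(
        {
            "type": "dense",
            "name": "out",
            "activation": "softmax",
            "weight_shape": list(w["out_W"].shape),
            "weights": w["out_W"].astype(float).tolist(),
            "bias": w["out_b"].astype(float).tolist(),
        }
    )
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "class_order": list(CLASS_ORDER),
        "input_shape": [spec.input_height, spec.input_width, 1],
        "spec": {
            "input_height": spec.input_height,
            "input_width": spec.input_width,
            "n_blocks": spec.n_blocks,
            "filters": spec.filters,
            "kernel_size": spec.kernel_size,
            "dense1": spec.dense1,
            "dense2": spec.dense2,
            "dropout_rate": spec.dropout_rate,
            "n_classes": spec.n_classes,
        },
        "metadata": bundle.metadata,
        "layers": layers,
    }


def import_json(doc: dict | str) -> ModelBundle:
    """Rebuild a bundle, validating format, layer types, and shapes."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    if doc.get("format") != FORMAT_NAME:
        raise FormatError(f"unknown document format {doc.get('format')!r}")
    if doc.get("version") != FORMAT_VERSION:
        raise FormatError(f"unsupported document version {doc.get('version')!r}")
    try:
        spec = CnnSpec(**doc["spec"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"bad spec section: {exc}") from exc
    spec.validate()

    known = {"conv2d", "maxpool2d", "flatten", "dense", "dropout"}
    weights: dict[str, np.ndarray] = {}
    for layer in doc.get("layers", []):
        ltype = layer.get("type")
        if ltype not in known:
            raise FormatError(f"unknown layer type {ltype!r}")
        if ltype == "conv2d":
            if "kernel" not in layer or "bias" not in layer:
                raise FormatError(f"conv layer {layer.get('name')} missing arrays")
            kern = np.asarray(layer["kernel"], dtype=np.float32)
            if list(kern.shape) != list(layer.get("kernel_shape", kern.shape)):
                raise FormatError(f"kernel shape mismatch in {layer.get('name')}")
            weights[f"{layer['name']}_W"] = kern
            weights[f"{layer['name']}_b"] = np.asarray(layer["bias"], dtype=np.float32)
        elif ltype == "dense":
            if "weights" not in layer or "bias" not in layer:
                raise FormatError(f"dense layer {layer.get('name')} missing arrays")
            mat = np.asarray(layer["weights"], dtype=np.float32)
            if list(mat.shape) != list(layer.get("weight_shape", mat.shape)):
                raise FormatError(f"weight shape mismatch in {layer.get('name')}")
            weights[f"{layer['name']}_W"] = mat
            weights[f"{layer['name']}_b"] = np.asarray(layer["bias"], dtype=np.float32)

    try:
        validate_weights(spec, weights)
    except Exception as exc:
        raise FormatError(str(exc)) from exc
    return ModelBundle(spec=spec, weights=weights, metadata=doc.get("metadata", {}))


def save_json(bundle: ModelBundle, path: str | Path) -> None:
    Path(path).write_text(json.dumps(export_json(bundle)))


def load_json(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != FORMAT_NAME:
        raise FormatError(f"{path}: unknown document format")
    return doc
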