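"""Independent forward-pass inference from the JSON model document.

This engine mirrors the deployed on-device predictor: it consumes only the
serialized document (never the trainer's state) and computes the forward
pass with deliberately different numerics and code than the training
implementation — shift-and-add convolution, slice-wise max-pooling, float64
accumulation — so agreement with the trainer is a genuine cross-check of
the serialization and of both forward passes. Dropout is inactive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InferenceError(ValueError):
    """Input image incompatible with the model document."""


@dataclass
class Prediction:
    p_nonaf: float
    p_af: float
    cutoff: float = 0.5

    @property
    def label(self) -> int:
        """1 (AF-risk) iff the AF probability reaches the cutoff."""
        return int(self.p_af >= self.cutoff)

    def __post_init__(self) -> None:
        if abs(self.p_nonaf + self.p_af - 1.0) > 1e-6:
            raise InferenceError("class probabilities must sum to 1")


def _conv_same(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded 2-D convolution by shift-and-add over kernel offsets."""
    h, w, cin = x.shape
    kh, kw, kcin, cout = kernel.shape
    if kcin != cin:
        raise InferenceError(f"channel mismatch: input {cin}, kernel {kcin}")
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((h + 2 * ph, w + 2 * pw, cin))
    xp[ph : ph + h, pw : pw + w, :] = x
    out = np.zeros((h, w, cout))
    for di in range(kh):
        for dj in range(kw):
            out += xp[di : di + h, dj : dj + w, :] @ kernel[di, dj]
    return out + bias


def _maxpool2(x: np.ndarray) -> np.ndarray:
    a = np.maximum(x[0::2, 0::2, :], x[1::2, 0::2, :])
    b = np.maximum(x[0::2, 1::2, :], x[1::2, 1::2, :])
    return np.maximum(a, b)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _forward(doc: dict, image: np.ndarray) -> np.ndarray:
    expected = tuple(doc["input_shape"][:2])
    x = np.asarray(image, dtype=float)
    if x.ndim == 3 and x.shape[-1] == 1:
        x = x[..., 0]
    if x.shape != expected:
        raise InferenceError(f"image shape {x.shape} != model input {expected}")
    act = x[..., None]
    for layer in doc["layers"]:
        lt = layer["type"]
        if lt == "conv2d":
            act = _conv_same(
                act,
                np.asarray(layer["kernel"], dtype=float),
                np.asarray(layer["bias"], dtype=float),
            )
            if layer.get("activation") == "relu":
                act = np.maximum(act, 0.0)
        elif lt == "maxpool2d":
            act = _maxpool2(act)
        elif lt == "flatten":
            act = act.reshape(-1)  # row-major HWC, as declared in the document
        elif lt == "dense":
            act = act @ np.asarray(layer["weights"], dtype=float) + np.asarray(
                layer["bias"], dtype=float
            )
            if layer.get("activation") == "relu":
                act = np.maximum(act, 0.0)
            elif layer.get("activation") == "softmax":
                act = _softmax(act)
        elif lt == "dropout":
            continue  # inference-time no-op
        else:
            raise InferenceError(f"unknown layer type {lt!r}")
    return act


def infer(doc: dict, image, cutoff: float = 0.5) -> Prediction:
    """Predict AF risk for one composite image from the JSON document."""
    pixels = getattr(image, "pixels", image)
    probs = _forward(doc, pixels)
    order = doc.get("class_order", ["nonAF", "AF"])
    p_af = float(probs[order.index("AF")])
    p_nonaf = float(probs[order.index("nonAF")])
    return Prediction(p_nonaf=p_nonaf, p_af=p_af, cutoff=cutoff)


def predict_proba(doc: dict, images) -> np.ndarray:
    """(n, 2) class probabilities, column order as in the document."""
    return np.stack([_forward(doc, getattr(im, "pixels", im)) for im in images])
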