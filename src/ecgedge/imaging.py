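"""Averaged beats to composite binary images (the CNN input).

Each 1 s lead waveform is compressed along time (anti-alias filtered
polyphase resampling, 500 -> tile_width points) and amplitude (clip to
+/- amp_clip mV, affine map to pixel rows), drawn as a connected binary
trace in a tile, and the 12 tiles are arranged in a 4-row x 3-column
mosaic. Default tiles are 32 x 32, so the composite is 128 x 96 — divisible
by 2^4 to match the CNN's four pooling stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import signal as sps

from .records import LEAD_NAMES
from .preprocess import AveragedBeat

#: row-major 4x3 lead layout: limb leads then precordial
DEFAULT_LAYOUT: tuple[tuple[str, str, str], ...] = (
    ("I", "II", "III"),
    ("aVR", "aVL", "aVF"),
    ("V1", "V2", "V3"),
    ("V4", "V5", "V6"),
)


class ImagingError(ValueError):
    """Invalid imaging configuration or input."""


@dataclass
class ImagingConfig:
    tile_height: int = 32
    tile_width: int = 32
    amp_clip_mv: float = 1.5
    layout: tuple[tuple[str, str, str], ...] = field(default=DEFAULT_LAYOUT)

    @property
    def composite_height(self) -> int:
        return 4 * self.tile_height

    @property
    def composite_width(self) -> int:
        return 3 * self.tile_width

    def validate(self) -> None:
        if self.amp_clip_mv <= 0:
            raise ImagingError("amp_clip_mv must be > 0")
        if self.composite_height % 16 or self.composite_width % 16:
            raise ImagingError("composite dims must be divisible by 2^4 (four poolings)")
        flat = [name for row in self.layout for name in row]
        if sorted(flat) != sorted(LEAD_NAMES):
            raise ImagingError("layout must contain each of the 12 leads exactly once")


@dataclass
class CompositeImage:
    pixels: np.ndarray  # (4*tile_h, 3*tile_w) uint8 in {0,1}
    config: ImagingConfig
    patient_id: str = ""
    source: str = "averaged"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        expected = (self.config.composite_height, self.config.composite_width)
        if self.pixels.shape != expected:
            raise ImagingError(f"composite shape {self.pixels.shape} != {expected}")
        if not np.isin(self.pixels, (0, 1)).all():
            raise ImagingError("composite must be binary")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def compress_beat(lead_samples: np.ndarray, config: ImagingConfig) -> np.ndarray:
    """Compress one 500-sample lead waveform to ``tile_width`` row indices.

    Time axis: zero-phase anti-alias low-pass (steep Butterworth at the
    target Nyquist) then uniform endpoint-inclusive resampling. Amplitude
    axis: clip to [-amp_clip, +amp_clip] and affine-map so +clip is row 0
    (top) and 0 mV lands on the middle row, rounding half up.
    """
    config.validate()
    x = np.asarray(lead_samples, dtype=float)
    if x.ndim != 1 or x.size != 500:
        raise ImagingError(f"expected a 500-sample lead, got shape {x.shape}")
    if config.tile_width > 500:
        raise ImagingError("tile_width > 500 would require upsampling")
    if config.tile_width < 500:
        # the 1 s beat resampled to tile_width points has Nyquist tile_width/2 Hz;
        # a steep (order-8) filter at that edge preserves in-band P-wave detail
        sos = sps.butter(8, 0.5 * config.tile_width, "lowpass", fs=500, output="sos")
        smooth = sps.sosfiltfilt(sos, x)
        grid = np.linspace(0.0, x.size - 1.0, config.tile_width)
        x = np.interp(grid, np.arange(x.size), smooth)
    clip = config.amp_clip_mv
    x = np.clip(x, -clip, clip)
    rows = _round_half_up((clip - x) / (2.0 * clip) * (config.tile_height - 1))
    return np.clip(rows, 0, config.tile_height - 1)


def binarize_tile(rows: np.ndarray, config: ImagingConfig) -> np.ndarray:
    """Draw the trace as foreground 1 on a 0 background.

    Each column gets its sample pixel; between adjacent columns the
    vertical gap is filled, each column extending from its sample row
    toward the midpoint of the step, so the trace is 8-connected.
    """
    rows = np.asarray(rows, dtype=int)
    h, w = config.tile_height, config.tile_width
    if rows.size != w or rows.min() < 0 or rows.max() >= h:
        raise ImagingError("row indices out of range for the tile")
    tile = np.zeros((h, w), dtype=np.uint8)
    tile[rows, np.arange(w)] = 1
    for j in range(w - 1):
        r0, r1 = rows[j], rows[j + 1]
        if abs(int(r1) - int(r0)) > 1:
            mid = (r0 + r1) / 2.0
            lo0, hi0 = sorted((r0, int(np.floor(mid)) if r0 < r1 else int(np.ceil(mid))))
            lo1, hi1 = sorted((int(np.ceil(mid)) if r0 < r1 else int(np.floor(mid)), r1))
            tile[lo0 : hi0 + 1, j] = 1
            tile[lo1 : hi1 + 1, j + 1] = 1
    return tile


def beat_tiles(beat: AveragedBeat, config: ImagingConfig) -> dict[str, np.ndarray]:
    return {
        name: binarize_tile(compress_beat(beat.samples[i], config), config)
        for i, name in enumerate(LEAD_NAMES)
    }


def compose_image(
    tiles: dict[str, np.ndarray],
    config: ImagingConfig,
    patient_id: str = "",
    source: str = "averaged",
) -> CompositeImage:
    """Arrange the 12 lead tiles into the 4x3 mosaic (no padding)."""
    config.validate()
    if sorted(tiles) != sorted(LEAD_NAMES):
        raise ImagingError(f"need exactly the 12 leads, got {sorted(tiles)}")
    h, w = config.tile_height, config.tile_width
    pixels = np.zeros((config.composite_height, config.composite_width), dtype=np.uint8)
    for r, row in enumerate(config.layout):
        for c, name in enumerate(row):
            tile = np.asarray(tiles[name])
            if tile.shape != (h, w):
                raise ImagingError(f"tile {name} shaped {tile.shape}, expected {(h, w)}")
            pixels[r * h : (r + 1) * h, c * w : (c + 1) * w] = tile
    return CompositeImage(pixels=pixels, config=config, patient_id=patient_id, source=source)


def beat_to_image(
    beat: AveragedBeat, config: ImagingConfig | None = None
) -> CompositeImage:
    """Full averaged-beat -> composite-binary-image conversion."""
    config = config or ImagingConfig()
    return compose_image(
        beat_tiles(beat, config), config, patient_id=beat.patient_id, source=beat.source
    )


def image_to_png(image: CompositeImage, path: str | Path) -> None:
    """Foreground -> white (255), background -> black (0); 8-bit grayscale."""
    Image.fromarray((image.pixels * 255).astype(np.uint8), mode="L").save(Path(path))


def image_from_png(path: str | Path, config: ImagingConfig | None = None) -> CompositeImage:
    config = config or ImagingConfig()
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    if not np.isin(arr, (0, 255)).all():
        raise ImagingError(f"{path}: PNG is not binary (values other than 0/255)")
    return CompositeImage(pixels=(arr == 255).astype(np.uint8), config=config)


def image_to_npy(image: CompositeImage, path: str | Path) -> None:
    np.save(Path(path), image.pixels)


def image_from_npy(path: str | Path, config: ImagingConfig | None = None) -> CompositeImage:
    config = config or ImagingConfig()
    return CompositeImage(pixels=np.load(Path(path)), config=config)
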