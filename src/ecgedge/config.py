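"""Pipeline configuration: one YAML document, one master seed.

The master seed fans out to stage-specific seeds (cohort generation,
splitting, weight init, training shuffles) so the whole pipeline is
reproducible from a single integer. Derived seeds stay below 2^31.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imaging import ImagingConfig
from .model.architecture import CnnSpec, TrainConfig
from .preprocess import FilterBank
from .synth import AfEffect, NoiseAmps, SynthParams

_STAGE_OFFSETS = {"cohort": 1, "split": 2, "init": 3, "train": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    output_dir: str = "out"
    records_dir: str | None = None  # default: <output_dir>/cohort/records
    metadata_csv: str | None = None
    seed: int = 0
    augment: bool = True  # add dominant-waveform images in train/val
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    cutoff: float | None = None  # None -> optimize on the test scores
    log_level: str = "INFO"
    synth: SynthParams = field(default_factory=SynthParams)
    filters: FilterBank = field(default_factory=FilterBank)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    cnn: CnnSpec = field(default_factory=CnnSpec)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        self.split_ratios = tuple(self.split_ratios)
        # one master seed governs every stochastic stage
        self.synth.seed = stage_seed(self.seed, "cohort")
        self.train.seed = stage_seed(self.seed, "train")
        self.imaging.validate()
        self.cnn.validate()
        self.train.validate()
        self.synth.validate()
        self.filters.validate()

    def config_hash(self) -> str:
        blob = json.dumps(to_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["imaging"]["layout"] = [list(r) for r in cfg.imaging.layout]
    d["split_ratios"] = list(cfg.split_ratios)
    d["synth"]["age_range"] = list(cfg.synth.age_range)
    return d


def from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "synth" in d:
        s = dict(d["synth"])
        if "af_effect" in s:
            s["af_effect"] = AfEffect(**s["af_effect"])
        if "noise_amps" in s:
            s["noise_amps"] = NoiseAmps(**s["noise_amps"])
        if "age_range" in s:
            s["age_range"] = tuple(s["age_range"])
        d["synth"] = SynthParams(**s)
    if "filters" in d:
        d["filters"] = FilterBank(**d["filters"])
    if "imaging" in d:
        im = dict(d["imaging"])
        if "layout" in im:
            im["layout"] = tuple(tuple(r) for r in im["layout"])
        d["imaging"] = ImagingConfig(**im)
    if "cnn" in d:
        d["cnn"] = CnnSpec(**d["cnn"])
    if "train" in d:
        d["train"] = TrainConfig(**d["train"])
    if "split_ratios" in d:
        d["split_ratios"] = tuple(d["split_ratios"])
    return PipelineConfig(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=False))
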