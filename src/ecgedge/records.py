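"""Core ECG record container and plain-text I/O.

A record is a 10 s, 12-lead ECG sampled at 500 Hz with amplitudes in mV,
plus the bookkeeping the downstream pipeline needs: which of the four
device noise filters have already been applied, the patient id, and an
optional AF-risk label. Records are written as a per-lead CSV (5000 rows,
one column per lead) with a JSON sidecar for the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)
N_LEADS = 12
FS = 500
RECORD_SECONDS = 10
RECORD_SAMPLES = FS * RECORD_SECONDS

#: the four noise-filter families provided on the acquisition device
FILTER_FLAGS = frozenset({"powerline", "emg", "drift", "hf"})


class RecordError(ValueError):
    """Invalid record contents or metadata."""


@dataclass
class EcgRecord:
    """One 12-lead, 10 s ECG at 500 Hz (mV)."""

    samples: np.ndarray
    fs: int = FS
    lead_names: tuple[str, ...] = LEAD_NAMES
    applied_filters: frozenset[str] = frozenset()
    patient_id: str = ""
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.applied_filters = frozenset(self.applied_filters)
        self.validate()

    def validate(self) -> None:
        if self.samples.shape != (N_LEADS, RECORD_SAMPLES):
            raise RecordError(
                f"expected {N_LEADS}x{RECORD_SAMPLES} samples, got {self.samples.shape}"
            )
        if self.fs != FS:
            raise RecordError(f"sampling rate must be {FS} Hz, got {self.fs}")
        if tuple(self.lead_names) != LEAD_NAMES:
            raise RecordError(f"lead names must be {LEAD_NAMES}")
        if not self.applied_filters <= FILTER_FLAGS:
            raise RecordError(
                f"unknown filter flags: {set(self.applied_filters) - FILTER_FLAGS}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise RecordError("samples contain non-finite values")

    def lead(self, name: str) -> np.ndarray:
        return self.samples[LEAD_NAMES.index(name)]

    def with_samples(self, samples: np.ndarray, applied: frozenset[str]) -> "EcgRecord":
        return replace(self, samples=samples, applied_filters=frozenset(applied))


def write_record_csv(record: EcgRecord, path: str | Path) -> None:
    """Write one record as per-lead CSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(record.samples.T, columns=list(LEAD_NAMES))
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "fs": record.fs,
        "applied_filters": sorted(record.applied_filters),
        "patient_id": record.patient_id,
        "label": record.label,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_record_csv(path: str | Path) -> EcgRecord:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != list(LEAD_NAMES):
        raise RecordError(f"{path}: columns {list(df.columns)} != {list(LEAD_NAMES)}")
    meta_path = path.with_suffix(".json")
    fs, applied, pid, label = FS, frozenset(), path.stem, None
    if meta_path.exists():
        sidecar = json.loads(meta_path.read_text())
        fs = sidecar.get("fs", FS)
        applied = frozenset(sidecar.get("applied_filters", []))
        pid = sidecar.get("patient_id", pid)
        label = sidecar.get("label")
    return EcgRecord(
        samples=df.to_numpy().T,
        fs=fs,
        applied_filters=applied,
        patient_id=pid,
        label=label,
    )
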