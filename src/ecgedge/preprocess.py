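"""Noise filtering, R-peak detection, and R-wave-triggered beat extraction.

The acquisition device offers four noise filters (power-line notch,
myoelectric low-pass, baseline-drift high-pass, high-frequency low-pass)
and records which ones the clinician enabled. To standardize inputs, the
pipeline applies exactly the filters that were *not* already applied, so
every record has seen all four. All filtering is zero-phase
(forward-backward) per lead.

Beat extraction aligns beats on the R wave: a Pan-Tompkins-style detector
(band-pass, derivative, squaring, moving integration, adaptive threshold)
runs on lead II with an all-lead RMS fallback, ectopic/corrupted beats are
rejected against a median template, and the accepted windows (300 ms
before R to 700 ms after) are averaged pointwise into a 1 s, 12-lead
template. The single most representative real beat — the one with the
highest mean lead-II cross-correlation to the other accepted beats — is
the "dominant" waveform, used to double the training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import FILTER_FLAGS, FS, LEAD_NAMES, EcgRecord

#: averaging window around R: 300 ms before, 700 ms after (1 s total)
DEFAULT_WINDOW_MS = (300, 700)
LEAD_II = LEAD_NAMES.index("II")


class QualityError(RuntimeError):
    """Record cannot support beat averaging (too few usable beats)."""


class FilterConfigError(ValueError):
    """Unstable or out-of-range filter design."""


@dataclass
class FilterBank:
    """The four device filters. Defaults are standard clinical settings
    for a 50 Hz mains region; the notch center is configurable to 60 Hz."""

    powerline_hz: float = 50.0
    powerline_q: float = 30.0
    emg_cutoff_hz: float = 35.0
    emg_order: int = 4
    drift_cutoff_hz: float = 0.67
    drift_order: int = 2
    hf_cutoff_hz: float = 100.0
    hf_order: int = 4

    def validate(self, fs: int = FS) -> None:
        nyq = fs / 2.0
        for c in (self.powerline_hz, self.emg_cutoff_hz, self.drift_cutoff_hz, self.hf_cutoff_hz):
            if not 0 < c < nyq:
                raise FilterConfigError(f"cutoff {c} Hz outside (0, {nyq})")
        if self.powerline_hz not in (50.0, 60.0):
            raise FilterConfigError("power-line notch center must be 50 or 60 Hz")

    def design(self, name: str, fs: int = FS):
        if name == "powerline":
            b, a = sps.iirnotch(self.powerline_hz, self.powerline_q, fs=fs)
            return sps.tf2sos(b, a)
        if name == "emg":
            return sps.butter(self.emg_order, self.emg_cutoff_hz, "lowpass", fs=fs, output="sos")
        if name == "drift":
            return sps.butter(self.drift_order, self.drift_cutoff_hz, "highpass", fs=fs, output="sos")
        if name == "hf":
            return sps.butter(self.hf_order, self.hf_cutoff_hz, "lowpass", fs=fs, output="sos")
        raise KeyError(name)


@dataclass
class AveragedBeat:
    """1 s, 12-lead beat template aligned on the R wave."""

    samples: np.ndarray  # (12, 500) mV
    r_index: int
    n_beats_used: int
    source: str  # "averaged" | "dominant"
    patient_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (12, FS):
            raise ValueError(f"averaged beat must be 12x{FS}, got {self.samples.shape}")
        if self.n_beats_used < 1:
            raise ValueError("n_beats_used must be >= 1")
        if self.source not in ("averaged", "dominant"):
            raise ValueError(f"unknown source {self.source!r}")


def apply_missing_filters(record: EcgRecord, bank: FilterBank | None = None) -> EcgRecord:
    """Apply exactly the filters not yet flagged on the record; the result
    carries all four flags. Idempotent: a second call is a no-op."""
    bank = bank or FilterBank()
    bank.validate(record.fs)
    missing = FILTER_FLAGS - record.applied_filters
    samples = record.samples
    for name in ("powerline", "emg", "drift", "hf"):  # deterministic order
        if name in missing:
            sos = bank.design(name, record.fs)
            samples = sps.sosfiltfilt(sos, samples, axis=1)
    return record.with_samples(samples, FILTER_FLAGS)


def _pan_tompkins_channel(x: np.ndarray, fs: int) -> np.ndarray:
    sos = sps.butter(2, [5.0, 15.0], "bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = int(0.150 * fs)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    return integ, bp


def _detect_on_channel(x: np.ndarray, fs: int) -> list[int]:
    integ, bp = _pan_tompkins_channel(x, fs)
    if np.max(integ) <= 0:
        return []
    dist = int(0.200 * fs)  # refractory spacing
    cand, _ = sps.find_peaks(integ, distance=dist)
    if cand.size == 0:
        return []
    # adaptive threshold: a fraction of the median of the strongest candidates
    top = np.sort(integ[cand])[::-1][: max(3, cand.size // 2)]
    thr = 0.25 * np.median(top)
    cand = cand[integ[cand] >= thr]
    # refine each candidate to the local extremum of the band-passed signal
    half = int(0.075 * fs)
    peaks = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, x.size)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = sorted(set(peaks))
    # enforce refractory spacing after refinement (keep the stronger of close pairs)
    out: list[int] = []
    for p in peaks:
        if out and p - out[-1] < dist:
            if np.abs(bp[p]) > np.abs(bp[out[-1]]):
                out[-1] = p
        else:
            out.append(p)
    return out


def detect_r_peaks(record: EcgRecord) -> list[int]:
    """Pan-Tompkins-style R detection on lead II; falls back to the RMS
    across all 12 leads when lead II yields fewer than 3 beats."""
    peaks = _detect_on_channel(record.samples[LEAD_II], record.fs)
    if len(peaks) < 3:
        rms = np.sqrt(np.mean(record.samples**2, axis=0))
        peaks = _detect_on_channel(rms, record.fs)
    if len(peaks) < 3:
        raise QualityError(
            f"only {len(peaks)} beats detected; signal averaging needs >= 3"
        )
    return peaks


def _window_bounds(r: int, window_ms: tuple[int, int], fs: int) -> tuple[int, int]:
    return r - int(window_ms[0] * fs / 1000), r + int(window_ms[1] * fs / 1000)


def _full_window_peaks(
    r_peaks: list[int], n_samples: int, window_ms: tuple[int, int], fs: int
) -> list[int]:
    out = []
    for r in r_peaks:
        lo, hi = _window_bounds(r, window_ms, fs)
        if lo >= 0 and hi <= n_samples:
            out.append(r)
    return out


def reject_ectopic(
    record: EcgRecord,
    r_peaks: list[int],
    corr_threshold: float = 0.8,
    rr_tolerance: float = 0.25,
    window_ms: tuple[int, int] = DEFAULT_WINDOW_MS,
) -> list[int]:
    """Drop beats that look ectopic or corrupted.

    A beat is rejected when its lead-II window correlates < ``corr_threshold``
    with the pointwise-median beat template, or when its RR interval deviates
    more than ``rr_tolerance`` from the median RR. Never returns empty for
    >= 3 input peaks: the beat closest to the median template is retained.
    """
    if len(r_peaks) < 3:
        raise QualityError("ectopic rejection needs >= 3 peaks")
    fs = record.fs
    peaks = _full_window_peaks(r_peaks, record.samples.shape[1], window_ms, fs)
    if not peaks:
        return []
    lead2 = record.samples[LEAD_II]
    wins = np.stack([lead2[slice(*_window_bounds(r, window_ms, fs))] for r in peaks])
    template = np.median(wins, axis=0)

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        den = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / den) if den > 0 else 1.0

    corrs = np.array([_corr(w, template) for w in wins])

    rr = np.diff(r_peaks)
    med_rr = np.median(rr) if rr.size else 0.0
    rr_ok = np.ones(len(peaks), dtype=bool)
    if med_rr > 0:
        idx_of = {r: k for k, r in enumerate(r_peaks)}
        for j, r in enumerate(peaks):
            k = idx_of[r]
            gaps = []
            if k > 0:
                gaps.append(r_peaks[k] - r_peaks[k - 1])
            if k < len(r_peaks) - 1:
                gaps.append(r_peaks[k + 1] - r_peaks[k])
            # a beat is on-time if at least one adjacent interval is regular
            rr_ok[j] = any(abs(g - med_rr) <= rr_tolerance * med_rr for g in gaps)

    accepted = [r for j, r in enumerate(peaks) if corrs[j] >= corr_threshold and rr_ok[j]]
    if not accepted:
        accepted = [peaks[int(np.argmax(corrs))]]
    return accepted


def average_beats(
    record: EcgRecord,
    r_peaks: list[int],
    window_ms: tuple[int, int] = DEFAULT_WINDOW_MS,
) -> AveragedBeat:
    """Pointwise mean of the accepted beat windows, per lead. Beats whose
    window exceeds the record bounds are skipped."""
    if window_ms[0] + window_ms[1] != 1000:
        raise ValueError("averaging window must total 1000 ms")
    fs = record.fs
    peaks = _full_window_peaks(r_peaks, record.samples.shape[1], window_ms, fs)
    if not peaks:
        raise QualityError("no beat with a complete window; cannot average")
    wins = np.stack(
        [record.samples[:, slice(*_window_bounds(r, window_ms, fs))] for r in peaks]
    )
    return AveragedBeat(
        samples=wins.mean(axis=0),
        r_index=int(window_ms[0] * fs / 1000),
        n_beats_used=len(peaks),
        source="averaged",
        patient_id=record.patient_id,
        label=record.label,
    )


def dominant_beat(
    record: EcgRecord,
    r_peaks: list[int],
    window_ms: tuple[int, int] = DEFAULT_WINDOW_MS,
) -> AveragedBeat:
    """The single real beat maximizing mean lead-II cross-correlation with
    the other accepted beats (the window is applied to all 12 leads)."""
    fs = record.fs
    peaks = _full_window_peaks(r_peaks, record.samples.shape[1], window_ms, fs)
    if not peaks:
        raise QualityError("no beat with a complete window")
    if len(peaks) == 1:
        best = peaks[0]
    else:
        lead2 = record.samples[LEAD_II]
        wins = np.stack([lead2[slice(*_window_bounds(r, window_ms, fs))] for r in peaks])
        centered = wins - wins.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        norms[norms == 0] = 1.0
        unit = centered / norms[:, None]
        cmat = unit @ unit.T
        mean_corr = (cmat.sum(axis=1) - 1.0) / (len(peaks) - 1)
        best = peaks[int(np.argmax(mean_corr))]
    lo, hi = _window_bounds(best, window_ms, fs)
    return AveragedBeat(
        samples=record.samples[:, lo:hi].copy(),
        r_index=int(window_ms[0] * fs / 1000),
        n_beats_used=len(peaks),
        source="dominant",
        patient_id=record.patient_id,
        label=record.label,
    )


def write_beat_csv(beat: AveragedBeat, path: str | Path) -> None:
    """500 rows x 12 lead columns, with a JSON sidecar for the metadata."""
    path = Path(path)
    pd.DataFrame(beat.samples.T, columns=list(LEAD_NAMES)).to_csv(
        path, index=False, float_format="%.6f"
    )
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "r_index": beat.r_index,
                "n_beats_used": beat.n_beats_used,
                "source": beat.source,
                "patient_id": beat.patient_id,
                "label": beat.label,
            },
            indent=1,
        )
    )


def read_beat_csv(path: str | Path) -> AveragedBeat:
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(path.with_suffix(".json").read_text())
    return AveragedBeat(
        samples=df.to_numpy().T,
        r_index=side["r_index"],
        n_beats_used=side["n_beats_used"],
        source=side["source"],
        patient_id=side.get("patient_id", ""),
        label=side.get("label"),
    )
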