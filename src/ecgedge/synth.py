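"""Seeded synthetic 12-lead sinus-rhythm ECG cohorts.

The generator provides ground truth for every downstream stage: beats are
sums of per-wave Gaussians (P, Q, R, S, T) projected onto the 12 leads by a
fixed weight vector — an ECGSYN-style simplification in which the P wave is
the only thing that differs between classes. The AF-risk class perturbs P
morphology subtly (longer duration, lower amplitude, optional notch) while
QRS-T is identical by construction, emulating the premise that AF history
leaves faint atrial signatures on otherwise normal sinus-rhythm ECGs.

Records are 12 x 5000 samples (10 s at 500 Hz, mV): beats placed at
Gaussian-jittered RR intervals plus four additive noise families —
power-line (50 Hz sinusoid), myoelectric (band-limited 20-150 Hz),
baseline drift (0.05-0.5 Hz), and broadband high-frequency noise.

Reproducibility: patient ``i`` of a cohort draws from
``SeedSequence(master_seed, spawn_key=(i + 1,))`` so per-patient streams
are independent of insertion order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import FS, LEAD_NAMES, N_LEADS, RECORD_SAMPLES, EcgRecord, write_record_csv

BEAT_SAMPLES = FS  # 1 s beat template
BEAT_R_INDEX = 150  # R wave at 300 ms into the template
WAVES = ("P", "Q", "R", "S", "T")

#: onset/offset threshold (mV, lead II) used when measuring P duration
P_DURATION_THRESHOLD_MV = 0.01


class SynthError(ValueError):
    """Invalid generator parameters or an unsatisfiable record request."""


@dataclass
class WaveParams:
    """Sum-of-Gaussians beat morphology.

    ``amplitudes_mv`` are lead-II reference amplitudes; ``centers_ms`` are
    offsets from the R peak; ``widths_ms`` are Gaussian sigmas. The single
    ``lead_weights`` 12-vector projects the dipole-like waveform onto the
    leads (lead II weight 1 by convention).
    """

    amplitudes_mv: dict[str, float] = field(
        default_factory=lambda: {"P": 0.22, "Q": -0.10, "R": 1.10, "S": -0.25, "T": 0.35}
    )
    centers_ms: dict[str, float] = field(
        default_factory=lambda: {"P": -160.0, "Q": -25.0, "R": 0.0, "S": 30.0, "T": 280.0}
    )
    widths_ms: dict[str, float] = field(
        default_factory=lambda: {"P": 22.0, "Q": 8.0, "R": 10.0, "S": 9.0, "T": 55.0}
    )
    lead_weights: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.6, 1.0, 0.5, -0.8, 0.15, 0.75, -0.3, 0.5, 0.9, 1.1, 1.0, 0.85]
        )
    )

    def __post_init__(self) -> None:
        self.lead_weights = np.asarray(self.lead_weights, dtype=float)
        if self.lead_weights.shape != (N_LEADS,) or not np.all(
            np.isfinite(self.lead_weights)
        ):
            raise SynthError("lead_weights must be a finite 12-vector")
        for w in WAVES:
            if self.widths_ms[w] <= 0:
                raise SynthError(f"width of wave {w} must be > 0")
        if self.amplitudes_mv["R"] * self.lead_weights[LEAD_NAMES.index("II")] <= 0:
            if self.amplitudes_mv["R"] != 0:  # all-zero beats are allowed
                raise SynthError("R amplitude must be positive in lead II")


@dataclass
class AfEffect:
    """Class effect applied to the P wave of AF-risk patients only."""

    p_duration_delta_ms: float = 20.0
    p_amplitude_scale: float = 0.8
    p_notch_depth_mv: float = 0.0

    @classmethod
    def none(cls) -> "AfEffect":
        return cls(0.0, 1.0, 0.0)


@dataclass
class NoiseAmps:
    """Additive noise levels (mV): peak for deterministic waveforms
    (power line, drift), RMS for stochastic ones (EMG, HF)."""

    powerline_mv: float = 0.05
    emg_mv: float = 0.03
    baseline_mv: float = 0.10
    hf_mv: float = 0.02

    def validate(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise SynthError(f"noise amplitude {name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseAmps":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class SynthParams:
    """Cohort-level generator settings."""

    n_patients: int = 400
    prevalence: float = 0.5
    rr_mean_ms: float = 800.0
    rr_sd_ms: float = 40.0
    af_effect: AfEffect = field(default_factory=AfEffect)
    noise_amps: NoiseAmps = field(default_factory=NoiseAmps)
    age_range: tuple[int, int] = (41, 90)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise SynthError("prevalence must be in [0, 1]")
        if self.rr_mean_ms <= 0:
            raise SynthError("rr_mean_ms must be > 0")
        if self.age_range[0] < 40:
            raise SynthError("age_range low must be >= 40")
        self.noise_amps.validate()


@dataclass
class SynthCohort:
    records: list[EcgRecord]
    labels: np.ndarray
    metadata: pd.DataFrame


def _gauss(t_ms: np.ndarray, amp: float, center: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)


def simulate_beat(
    wave_params: WaveParams,
    label: int = 0,
    af_effect: AfEffect | None = None,
    length: int = BEAT_SAMPLES,
) -> np.ndarray:
    """Deterministic 12 x ``length`` beat template (mV), R at ``BEAT_R_INDEX``.

    For ``label == 1`` (AF-risk) the P wave is widened so that its
    threshold-crossing duration (at 0.01 mV in lead II) grows by
    ``p_duration_delta_ms``, its amplitude is scaled, and an optional
    notch is subtracted at the P center; QRS-T is identical between classes.
    """
    if length != BEAT_SAMPLES:
        raise SynthError("beat length must correspond to 1 s at 500 Hz")
    af_effect = af_effect or AfEffect.none()
    t_ms = (np.arange(length) - BEAT_R_INDEX) / FS * 1000.0

    base = np.zeros(length)
    for w in ("Q", "R", "S", "T"):
        base += _gauss(
            t_ms, wave_params.amplitudes_mv[w], wave_params.centers_ms[w], wave_params.widths_ms[w]
        )

    p_amp = wave_params.amplitudes_mv["P"]
    p_sigma = wave_params.widths_ms["P"]
    p_center = wave_params.centers_ms["P"]
    if label == 1 and p_amp != 0:
        # widen sigma so the threshold-crossing duration grows by the delta
        a2 = abs(p_amp)
        if a2 > P_DURATION_THRESHOLD_MV and af_effect.p_duration_delta_ms != 0:
            d0 = 2.0 * p_sigma * np.sqrt(2.0 * np.log(a2 / P_DURATION_THRESHOLD_MV))
            p_sigma *= (d0 + af_effect.p_duration_delta_ms) / d0
        p_amp *= af_effect.p_amplitude_scale
    p_wave = _gauss(t_ms, p_amp, p_center, p_sigma)
    if label == 1 and af_effect.p_notch_depth_mv != 0:
        p_wave -= _gauss(t_ms, af_effect.p_notch_depth_mv, p_center, p_sigma / 3.0)

    return np.outer(wave_params.lead_weights, base + p_wave)


def p_wave_duration_ms(beat: np.ndarray, threshold: float = P_DURATION_THRESHOLD_MV) -> float:
    """Measured lead-II P duration: width of the supra-threshold run in the
    pre-QRS window (first 220 ms of the template)."""
    lead2 = beat[LEAD_NAMES.index("II"), : int(0.220 * FS)]
    above = np.flatnonzero(np.abs(lead2) > threshold)
    if above.size == 0:
        return 0.0
    return (above[-1] - above[0] + 1) / FS * 1000.0


def _emg_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, [20.0, 150.0], btype="bandpass", fs=FS, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    scale = np.sqrt(np.mean(shaped**2))
    return rms * shaped / scale if scale > 0 else shaped


def _baseline_drift(rng: np.random.Generator, t: np.ndarray, peak: float) -> np.ndarray:
    drift = np.zeros_like(t)
    for rel_amp in (0.6, 0.3, 0.1):
        f = rng.uniform(0.05, 0.5)
        phi = rng.uniform(0, 2 * np.pi)
        drift += rel_amp * np.sin(2 * np.pi * f * t + phi)
    m = np.max(np.abs(drift))
    return peak * drift / m if m > 0 else drift


def simulate_record(
    wave_params: WaveParams,
    synth_params: SynthParams,
    label: int,
    seed: int | np.random.Generator,
) -> EcgRecord:
    """One 10 s record: beats at jittered RR intervals plus the four noise
    families at the configured amplitudes. Ground-truth R-peak sample
    indices are kept in ``record.meta['r_peaks']``."""
    synth_params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rr_mean = synth_params.rr_mean_ms
    r_times_ms = [float(rng.uniform(250.0, 250.0 + rr_mean))]
    while True:
        rr = rng.normal(rr_mean, synth_params.rr_sd_ms)
        rr = max(rr, 300.0)  # physiologic refractory floor
        nxt = r_times_ms[-1] + rr
        if nxt >= RECORD_SAMPLES / FS * 1000.0:
            break
        r_times_ms.append(nxt)
    if len(r_times_ms) < 3:
        raise SynthError(
            f"rr_mean_ms={rr_mean} admits only {len(r_times_ms)} beats in 10 s (need >= 3)"
        )

    beat = simulate_beat(wave_params, label, synth_params.af_effect)
    samples = np.zeros((N_LEADS, RECORD_SAMPLES))
    r_peaks = []
    for t_ms in r_times_ms:
        r = int(round(t_ms / 1000.0 * FS))
        r_peaks.append(r)
        start = r - BEAT_R_INDEX
        lo, hi = max(start, 0), min(start + BEAT_SAMPLES, RECORD_SAMPLES)
        samples[:, lo:hi] += beat[:, lo - start : hi - start]

    na = synth_params.noise_amps
    t = np.arange(RECORD_SAMPLES) / FS
    if na.powerline_mv > 0:
        phi = rng.uniform(0, 2 * np.pi)
        samples += na.powerline_mv * np.sin(2 * np.pi * 50.0 * t + phi)[None, :]
    for lead in range(N_LEADS):
        if na.emg_mv > 0:
            samples[lead] += _emg_noise(rng, RECORD_SAMPLES, na.emg_mv)
        if na.baseline_mv > 0:
            samples[lead] += _baseline_drift(rng, t, na.baseline_mv)
        if na.hf_mv > 0:
            samples[lead] += na.hf_mv * rng.standard_normal(RECORD_SAMPLES)

    return EcgRecord(
        samples=samples,
        applied_filters=frozenset(),
        label=label,
        meta={"r_peaks": r_peaks},
    )


def _patient_rng(master_seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(i + 1,)))


def _jitter_wave_params(wave_params: WaveParams, rng: np.random.Generator) -> WaveParams:
    """Between-patient morphological variability: +/-15% wave amplitudes,
    +/-10% widths, +/-10% lead weights (keeps classes overlapping in any
    single feature while the mean P effect stays learnable)."""
    amps = {w: a * rng.uniform(0.85, 1.15) for w, a in wave_params.amplitudes_mv.items()}
    widths = {w: s * rng.uniform(0.9, 1.1) for w, s in wave_params.widths_ms.items()}
    weights = wave_params.lead_weights * rng.uniform(0.9, 1.1, size=N_LEADS)
    return replace(
        wave_params,
        amplitudes_mv=amps,
        widths_ms=widths,
        lead_weights=weights,
    )


def simulate_cohort(
    synth_params: SynthParams, wave_params: WaveParams | None = None
) -> SynthCohort:
    """One record per synthetic patient; labels match prevalence exactly
    (to rounding); fully reproducible from ``synth_params.seed``."""
    synth_params.validate()
    if synth_params.n_patients < 2:
        raise SynthError("need at least 2 patients")
    wave_params = wave_params or WaveParams()

    n = synth_params.n_patients
    n_pos = int(round(synth_params.prevalence * n))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    label_rng = np.random.default_rng(
        np.random.SeedSequence(synth_params.seed, spawn_key=(0,))
    )
    label_rng.shuffle(labels)

    records, rows = [], []
    for i in range(n):
        rng = _patient_rng(synth_params.seed, i)
        wp = _jitter_wave_params(wave_params, rng)
        params_i = replace(
            synth_params,
            rr_mean_ms=float(np.clip(rng.normal(synth_params.rr_mean_ms, 60.0), 600.0, 1200.0)),
        )
        rec = simulate_record(wp, params_i, int(labels[i]), rng)
        pid = f"P{i:05d}"
        age = int(rng.integers(synth_params.age_range[0], synth_params.age_range[1] + 1))
        sex = "M" if rng.random() < 0.5 else "F"
        rec.patient_id = pid
        rec.meta.update({"age": age, "sex": sex})
        records.append(rec)
        rows.append({"patient_id": pid, "age": age, "sex": sex, "label": int(labels[i])})

    return SynthCohort(records=records, labels=labels, metadata=pd.DataFrame(rows))


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> Path:
    """Write per-lead CSV records plus a metadata CSV; returns the directory."""
    outdir = Path(outdir)
    rec_dir = outdir / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        write_record_csv(rec, rec_dir / f"{rec.patient_id}.csv")
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    return outdir
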