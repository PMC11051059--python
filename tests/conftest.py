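import numpy as np
import pytest

from ecgedge.records import EcgRecord, FILTER_FLAGS, N_LEADS, RECORD_SAMPLES
from ecgedge.synth import (
    AfEffect,
    NoiseAmps,
    SynthParams,
    WaveParams,
    simulate_beat,
    simulate_record,
)


@pytest.fixture(scope="session")
def wave_params() -> WaveParams:
    return WaveParams()


@pytest.fixture(scope="session")
def quiet_params() -> SynthParams:
    """Noise-free, jitter-free generator settings (rr 1000 ms so beat
    windows tile the record without overlap)."""
    return SynthParams(
        n_patients=2,
        rr_mean_ms=1000.0,
        rr_sd_ms=0.0,
        noise_amps=NoiseAmps.silent(),
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_record(wave_params, quiet_params) -> EcgRecord:
    """Deterministic noise-free control record with ground-truth R peaks."""
    return simulate_record(wave_params, quiet_params, label=0, seed=11)


@pytest.fixture(scope="session")
def noisy_record(wave_params) -> EcgRecord:
    params = SynthParams(n_patients=2, rr_mean_ms=800.0, rr_sd_ms=40.0, seed=0)
    return simulate_record(wave_params, params, label=0, seed=12)


def make_record_from_windows(windows: list[np.ndarray], positions: list[int]) -> EcgRecord:
    """Place explicit 12x500 beat windows (R at sample 150 of the window)
    at the given R sample positions; zeros elsewhere."""
    samples = np.zeros((N_LEADS, RECORD_SAMPLES))
    for win, r in zip(windows, positions):
        start = r - 150
        samples[:, start : start + 500] += win
    return EcgRecord(samples=samples, applied_filters=frozenset(FILTER_FLAGS))


@pytest.fixture(scope="session")
def beat_template(wave_params) -> np.ndarray:
    return simulate_beat(wave_params, label=0, af_effect=AfEffect.none())
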