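"""Study-group definitions, SR-ECG selection windows, and exclusions.

The positive (AF) group is patients with at least one documented AF
episode: the *last* AF ECG is the index, and the candidate sinus-rhythm
ECG is the earliest SR record strictly after the index and within 2 years
of it, provided it precedes any catheter ablation. The control (non-AF)
group is patients with no AF documentation, no AF diagnostic code, and no
palpitation complaints: the *latest* SR ECG is the index and is selected
only when at least one additional SR ECG exists in the 5 years before it
(a guard against silently mislabeled paroxysmal AF). Both groups require
age over 40 at the selected ECG.

Selection is a pure function of a patient's history, and every exclusion
carries one machine-readable reason, applied in a fixed precedence order.
Year windows are implemented as 730 / 1826 days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

TWO_YEARS = dt.timedelta(days=730)
FIVE_YEARS = dt.timedelta(days=1826)
MIN_AGE_YEARS = 40


class Rhythm(str, Enum):
    SR = "SR"
    AF = "AF"
    OTHER = "other"


class ExclusionReason(str, Enum):
    PACED = "paced"
    POST_ABLATION_OR_SURGERY = "post_ablation_or_surgery"
    MITRAL_STENOSIS_OR_VALVE = "mitral_stenosis_or_valve"
    CARDIOGENIC_EMBOLISM = "cardiogenic_embolism"
    ARRHYTHMIA_LIST = "arrhythmia_exclusion_list"
    POOR_RECORDING = "poor_recording"
    ANTIARRHYTHMICS = "on_antiarrhythmics"
    AMBIGUOUS_DX = "af_code_without_af_ecg"
    PRE_INDEX_ONLY = "sr_only_before_index"
    NO_SR_IN_WINDOW = "no_sr_in_window"
    SINGLE_SR = "fewer_than_two_sr_in_5_years"
    UNDER_AGE = "age_not_over_40"
    NO_AF_EVENT = "no_af_event"
    HAS_AF_DOCUMENTATION = "af_documented_in_control_candidate"


@dataclass
class EcgEvent:
    patient_id: str
    timestamp: dt.date
    rhythm: Rhythm
    record_ref: str = ""


@dataclass
class PatientHistory:
    patient_id: str
    birth_date: dt.date
    sex: str
    events: list[EcgEvent] = field(default_factory=list)
    paced: bool = False
    post_ablation_date: dt.date | None = None
    heart_surgery: bool = False
    mitral_stenosis_or_valve: bool = False
    cardiogenic_embolism: bool = False
    palpitation_symptoms: bool = False
    af_dx_code: bool = False
    on_antiarrhythmics: bool = False
    arrhythmia_exclusion: bool = False
    poor_recording: bool = False

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.timestamp)

    def age_at(self, when: dt.date) -> int:
        years = when.year - self.birth_date.year
        if (when.month, when.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return years

    def events_of(self, rhythm: Rhythm) -> list[EcgEvent]:
        return [e for e in self.events if e.rhythm == rhythm]


@dataclass
class SelectionResult:
    patient_id: str
    group: str  # "AF" | "nonAF" | "excluded"
    selected: EcgEvent | None = None
    reason: ExclusionReason | None = None

    def __post_init__(self) -> None:
        if self.group in ("AF", "nonAF") and self.selected is None:
            raise ValueError("selected event required for an included patient")
        if self.group == "excluded" and self.reason is None:
            raise ValueError("excluded result must carry a reason")


def _excluded(pid: str, reason: ExclusionReason) -> SelectionResult:
    return SelectionResult(patient_id=pid, group="excluded", reason=reason)


def select_af_sr(history: PatientHistory) -> SelectionResult:
    """AF group: earliest SR ECG strictly after the last AF event, within
    2 years of it, and not after catheter ablation; age > 40 at the ECG."""
    af_events = history.events_of(Rhythm.AF)
    if not af_events:
        return _excluded(history.patient_id, ExclusionReason.NO_AF_EVENT)
    index = max(e.timestamp for e in af_events)
    sr = history.events_of(Rhythm.SR)
    in_window = [e for e in sr if index < e.timestamp <= index + TWO_YEARS]
    candidates = [
        e
        for e in in_window
        if history.post_ablation_date is None or e.timestamp <= history.post_ablation_date
    ]
    if not candidates:
        if in_window:
            return _excluded(history.patient_id, ExclusionReason.POST_ABLATION_OR_SURGERY)
        if sr and all(e.timestamp <= index for e in sr):
            return _excluded(history.patient_id, ExclusionReason.PRE_INDEX_ONLY)
        return _excluded(history.patient_id, ExclusionReason.NO_SR_IN_WINDOW)
    chosen = min(candidates, key=lambda e: e.timestamp)  # closest to the index
    if history.age_at(chosen.timestamp) <= MIN_AGE_YEARS:
        return _excluded(history.patient_id, ExclusionReason.UNDER_AGE)
    return SelectionResult(patient_id=history.patient_id, group="AF", selected=chosen)


def select_nonaf_sr(history: PatientHistory) -> SelectionResult:
    """Non-AF group: the latest SR ECG, selected only when at least one
    more SR ECG exists within the preceding 5 years; age > 40 at the index."""
    if history.events_of(Rhythm.AF) or history.af_dx_code or history.palpitation_symptoms:
        return _excluded(history.patient_id, ExclusionReason.HAS_AF_DOCUMENTATION)
    sr = history.events_of(Rhythm.SR)
    if not sr:
        return _excluded(history.patient_id, ExclusionReason.NO_SR_IN_WINDOW)
    index_event = max(sr, key=lambda e: e.timestamp)
    index = index_event.timestamp
    earlier = [e for e in sr if index - FIVE_YEARS <= e.timestamp < index]
    if not earlier:
        return _excluded(history.patient_id, ExclusionReason.SINGLE_SR)
    if history.age_at(index) <= MIN_AGE_YEARS:
        return _excluded(history.patient_id, ExclusionReason.UNDER_AGE)
    return SelectionResult(patient_id=history.patient_id, group="nonAF", selected=index_event)


def apply_exclusions(history: PatientHistory, result: SelectionResult) -> SelectionResult:
    """Flag-level exclusions in the fixed precedence order: the six listed
    criteria, then antiarrhythmic use, then ambiguous AF coding (an AF
    diagnostic code with no documented AF ECG)."""
    if result.group == "excluded":
        return result
    checks: list[tuple[bool, ExclusionReason]] = [
        (history.paced, ExclusionReason.PACED),
        (history.heart_surgery, ExclusionReason.POST_ABLATION_OR_SURGERY),
        (history.mitral_stenosis_or_valve, ExclusionReason.MITRAL_STENOSIS_OR_VALVE),
        (
            result.group == "nonAF" and history.cardiogenic_embolism,
            ExclusionReason.CARDIOGENIC_EMBOLISM,
        ),
        (history.arrhythmia_exclusion, ExclusionReason.ARRHYTHMIA_LIST),
        (history.poor_recording, ExclusionReason.POOR_RECORDING),
        (history.on_antiarrhythmics, ExclusionReason.ANTIARRHYTHMICS),
        (
            history.af_dx_code and not history.events_of(Rhythm.AF),
            ExclusionReason.AMBIGUOUS_DX,
        ),
    ]
    for flagged, reason in checks:
        if flagged:
            return _excluded(history.patient_id, reason)
    return result


def classify_patient(history: PatientHistory) -> SelectionResult:
    """Full group assignment: AF-group selection when AF is documented,
    control-group selection otherwise, then the flag exclusions."""
    if history.events_of(Rhythm.AF):
        result = select_af_sr(history)
    else:
        result = select_nonaf_sr(history)
    return apply_exclusions(history, result)


def build_splits(
    patients: list[tuple[str, int]],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Patient-level, class-balanced train/val/test split.

    ``patients`` is (patient_id, label). The majority class is randomly
    downsampled to the minority count (seeded), then each class is
    shuffled and partitioned by ``ratios``. A patient appears in exactly
    one partition. Image augmentation (averaged + dominant) is applied by
    the pipeline inside train/val only, after this split.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for pid, label in patients:
        by_class[int(label)].append(pid)
    if min(len(by_class[0]), len(by_class[1])) < 2:
        raise ValueError("need at least 2 patients per class")
    n_per_class = min(len(by_class[0]), len(by_class[1]))

    splits: dict[str, set[str]] = {"train": set(), "val": set(), "test": set()}
    for label in (0, 1):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        ids = ids[:n_per_class]  # balanced downsampling of the majority class
        n_train = int(round(ratios[0] * n_per_class))
        n_val = int(round(ratios[1] * n_per_class))
        n_val = min(n_val, n_per_class - n_train)
        splits["train"].update(ids[:n_train])
        splits["val"].update(ids[n_train : n_train + n_val])
        splits["test"].update(ids[n_train + n_val :])
    return splits
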