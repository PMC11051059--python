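# Methods

## Problem setting

The package targets retrospective AF-risk detection from a *sinus-rhythm*
10 s, 12-lead ECG sampled at 500 Hz: the positive class is "history of
documented AF", not ongoing arrhythmia. The working hypothesis is that AF
remodels the atria enough to leave subtle P-wave-scale signatures on
otherwise normal SR ECGs. The pipeline converts each record into one small
binary image and classifies it with a CNN compact enough for an
electrocardiograph's ROM/RAM budget, with all statistics computed exactly.

## Synthetic cohort generator

Clinical data are unavailable, so the generator defines the study
conditions under which everything is developed and tested.

**Beat model.** Each beat is a sum of five Gaussians (P, Q, R, S, T) with
lead-II reference amplitudes (0.22, −0.10, 1.10, −0.25, 0.35) mV, centers
(−160, −25, 0, 30, 280) ms relative to the R peak, and widths (sigmas)
(22, 8, 10, 9, 55) ms — ordinary adult SR morphology. A single 12-vector
of projection weights maps the waveform onto the leads (lead II = 1,
aVR negative). This is an ECGSYN-style simplification chosen because it
gives *independent control of P-wave morphology*; it does not model
inter-wave dipole rotation, respiratory modulation, or realistic
precordial progression.

**Class effect.** For AF-risk patients only the P wave changes: its
threshold-crossing duration (0.01 mV in lead II) is widened by
+20 ms (sigma rescaling), its amplitude scaled ×0.8, and an optional notch
subtracted (off by default). QRS-T is identical between classes by
construction, so any downstream discrimination must come from atrial
morphology. The default effect size was chosen once: large enough to be
learnable from a ~400-patient desk-scale cohort, small enough to be
invisible in a single noisy lead (the per-patient amplitude jitter ranges
of the two classes overlap).

**Between-patient variability.** Wave amplitudes jitter ±15%, widths
±10%, lead weights ±10%, and the per-patient mean RR is drawn from
N(800, 60) ms clipped to [600, 1200] ms with 40 ms within-record RR sd.

**Noise.** Four additive families mirror the device's filter targets:
50 Hz power-line sinusoid (0.05 mV peak, common phase across leads),
band-limited 20–150 Hz myoelectric noise (0.03 mV RMS), 0.05–0.5 Hz
baseline wander (0.10 mV peak, three random sinusoids), and broadband
white high-frequency noise (0.02 mV RMS) — moderate levels typical of a
resting clinical recording.

**Reproducibility.** Patient *i* draws from
`SeedSequence(master_seed, spawn_key=(i+1,))`; cohorts are bit-identical
for a fixed seed and independent of patient insertion order.

**What passing tests do and do not show.** The generator validates the
*mechanics* of the pipeline (filtering, alignment, averaging, imaging,
learning, serialization, statistics) under a known ground truth. It does
not validate clinical performance: real AF signatures are not a clean
P-duration/amplitude shift, real noise is not stationary, and real cohorts
carry covariate structure the generator lacks.

## Preprocessing

- **Filter bank defaults** (all zero-phase `sosfiltfilt`): 50 Hz notch
  Q=30 (configurable to 60 Hz), 35 Hz order-4 low-pass (myoelectric),
  0.67 Hz order-2 high-pass (drift), 100 Hz order-4 low-pass (HF). The
  noise families are fixed by the device design; these cutoffs are
  standard clinical settings. Only the filters not flagged as already
  applied are run, making the operation idempotent.
- **R detection**: Pan–Tompkins-style chain (5–15 Hz band-pass,
  derivative, squaring, 150 ms moving integration, adaptive threshold at
  0.25× the median of the strongest candidates, 200 ms refractory) on
  lead II, refined to the local band-passed extremum; if lead II yields
  fewer than 3 beats the detector re-runs on the 12-lead RMS channel.
  Records with < 3 detected beats are rejected as unaverageable.
- **Ectopic rejection**: a beat is dropped when its lead-II window
  correlates < 0.8 with the pointwise-median template or when neither
  adjacent RR interval is within ±25% of the median RR (conventional
  signal-averaged-ECG practice). The rule never empties a record: the
  beat closest to the median template is always retained.
- **Averaging window**: 300 ms before R to 700 ms after (1 s total),
  covering the P wave and the full T wave at normal rates. Windows that
  would cross the record boundary are skipped.
- **Dominant waveform**: the accepted beat maximizing mean lead-II
  cross-correlation with the other accepted beats; used as a second
  training image per patient (train/val only — test patients contribute
  exactly one averaged image each).

## Imaging

Per lead: zero-phase order-8 Butterworth anti-alias low-pass at the
target Nyquist (16 Hz for 32-pixel tiles — steep enough to protect the
band edge without smearing the ≲12 Hz P wave), endpoint-inclusive uniform
resampling 500 → 32 samples, clip to ±1.5 mV, affine map to 32 rows (top
row = +clip; 0 mV lands on the middle row, rounding half up). The trace is drawn 8-connected: each column carries its sample pixel
and, across steps larger than one row, each of the two adjacent columns
fills vertically from its sample row to the step midpoint. Tiles are
composed row-major, limb leads then precordial
(I II III / aVR aVL aVF / V1 V2 V3 / V4 V5 V6), giving a 128 × 96 binary
image — divisible by 2⁴ so four pooling stages yield an 8 × 6 × 64
feature map. Tile size, clip, and layout are configurable; the defaults
balance P-wave visibility (one row ≈ 0.094 mV, one column ≈ 31 ms)
against the ~0.5 M-parameter model budget.

## Model

Architecture: four blocks of (3×3 conv, 64 filters, same-padding, ReLU,
2×2 max-pool), flatten (row-major H×W×C), dense 128 (ReLU), dense 64
(ReLU), dropout 0.5, dense 2 + softmax; class order is fixed (0 = non-AF,
1 = AF) and recorded in the JSON document. With the default 128 × 96
input this is exactly 513,154 parameters. The head widths and dropout
rate are package choices sized to keep the serialized model in the
few-MB range of an edge deployment.

Training: mini-batch Adam (β₁ 0.9, β₂ 0.999, ε 1e-7), batch 64, initial
lr 1e-4 with legacy per-update decay lr/(1 + 1e-6·step), categorical
cross-entropy, default 150 epochs; the weights of the epoch with the best
validation AUC are kept. Initialization is seeded He-normal with zero
biases. The implementation is pure NumPy (im2col GEMM for the
single-channel entry convolution, shifted batched matmuls for the deeper
ones, comparison-routed max-pool gradients, float32 throughout, scratch
buffers reused across steps); with a fixed seed, training is
bit-reproducible on a given platform, and a `deterministic` flag records
that contract in the config.

Serialization: a versioned, self-describing JSON document (layer list,
HWIO kernel order, HWC flatten order, class order, float32 weights —
lossless through decimal text). The independent inference engine reads
only this document and computes the forward pass with deliberately
different code and float64 numerics; agreement with the trainer within
1e-5 per class is asserted both in tests and as a built-in check of the
`evaluate` command. Dropout is inference-inactive.

## Cohort rules

Selection windows are implemented on calendar dates with 2 years = 730
days and 5 years = 1826 days; the index event itself is never selectable
(windows are open at the index, closed at the far end). Exclusions apply
in a fixed precedence order — paced rhythm; post-ablation/heart surgery;
mitral stenosis or valve replacement; cardiogenic embolism (controls
only); the configurable arrhythmia blacklist; poor recording; then
antiarrhythmic use; then an AF diagnostic code without ECG documentation
— so every excluded patient carries exactly one machine-readable reason.
Splits are patient-level and class-balanced: the majority class is
randomly downsampled (seeded), each class shuffled and partitioned by the
configured ratios; dominant-waveform augmentation happens strictly after
splitting and only inside train/val.

## Evaluation

- Binomial metrics use exact Clopper–Pearson beta-quantile intervals;
  precision's denominator is the predicted-positive count and is reported
  as missing when that count is zero.
- AUC is the Mann–Whitney statistic with half credit for ties; its CI
  uses DeLong's structural-components variance (normal approximation,
  truncated to [0, 1]).
- Cutoff optimization scans the midpoints of sorted unique scores for the
  smallest |sensitivity − specificity|, breaking ties toward the higher
  Youden index and then the lower cutoff; a score equal to the cutoff
  predicts positive.
- Fisher exact tests are two-sided by point-probability summation (the
  R convention); continuous variables get an equality-of-variance F-test
  paired with Student's pooled-variance t-test (Welch available as an
  option). Missing categorical values are excluded pairwise with their
  counts reported alongside.

## Numerical choices and degenerate inputs

Zero-amplitude beats are legal (all-zero records are rejected later by
the R detector, not the generator). Filters validate cutoffs against the
Nyquist limit at construction. The quantizer rounds half up so the 0 mV
baseline maps deterministically. Training refuses empty partitions and
single-class label vectors; zero-epoch training returns the initial
weights unchanged. JSON import validates format, version, layer types,
and every weight shape before constructing a model.

## Desk-scale problem sizes

The test-bench end-to-end run uses 400 synthetic patients
(320/40/40 train/val/test after balanced splitting) for 30 epochs without
augmentation; the reproduction script uses 320 patients for 20 epochs.
These sizes were chosen as the package's desk-scale defaults: large
enough for the default effect to be learnable with a CI excluding chance,
small enough to run on a single CPU in minutes.

## Known limitations

The generator's P-wave-centric class effect is an assumption for
testability, not a claim about what a clinically trained model keys on.
The beat model shares one projection vector across waves; precordial
morphology is therefore stylized. The arrhythmia exclusion list is a
configurable blacklist with no canonical contents. WFDB input is not
implemented — records are read and written as per-lead CSV with JSON
sidecars. No quantization, pruning, or on-device latency measurement is
included.
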