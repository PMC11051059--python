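# Complete annotated pipeline configuration for `ecgedge`.
# Every command reads the same file; one master seed drives every
# stochastic stage (cohort generation, splitting, weight init, training).

output_dir: out          # all artifacts are written under this directory
records_dir: null        # input records; default <output_dir>/cohort/records
metadata_csv: null       # optional external metadata table
seed: 1                  # master seed (stage seeds are derived from it)
augment: true            # add dominant-waveform images in train/val
split_ratios: [0.8, 0.1, 0.1]   # patient-level train/val/test fractions
cutoff: null             # decision threshold; null = optimize on test scores
log_level: INFO

synth:                   # synthetic cohort generator
  n_patients: 400
  prevalence: 0.5        # fraction of AF-risk patients
  rr_mean_ms: 800.0      # cohort mean RR interval
  rr_sd_ms: 40.0         # within-record RR jitter
  af_effect:             # P-wave-only class effect
    p_duration_delta_ms: 20.0   # widen P threshold-crossing duration
    p_amplitude_scale: 0.8      # scale P amplitude
    p_notch_depth_mv: 0.0       # optional P-wave notch (off by default)
  noise_amps:            # mV; peak for deterministic, RMS for stochastic
    powerline_mv: 0.05   # 50 Hz mains sinusoid
    emg_mv: 0.03         # band-limited 20-150 Hz myoelectric noise
    baseline_mv: 0.10    # 0.05-0.5 Hz wander
    hf_mv: 0.02          # broadband high-frequency noise
  age_range: [41, 90]    # patients must be over 40
  seed: 0                # overwritten by the master seed

filters:                 # the four device filters (zero-phase)
  powerline_hz: 50.0     # notch center (50 or 60)
  powerline_q: 30.0
  emg_cutoff_hz: 35.0
  emg_order: 4
  drift_cutoff_hz: 0.67
  drift_order: 2
  hf_cutoff_hz: 100.0
  hf_order: 4

imaging:                 # composite binary image
  tile_height: 32        # rows per lead tile
  tile_width: 32         # columns per lead tile (1 s of beat)
  amp_clip_mv: 1.5       # amplitude clip mapped onto tile height
  layout:                # 4 rows x 3 columns of lead names
    - [I, II, III]
    - [aVR, aVL, aVF]
    - [V1, V2, V3]
    - [V4, V5, V6]

cnn:                     # architecture (128x96 input -> 513,154 params)
  input_height: 128
  input_width: 96
  n_blocks: 4            # conv blocks: 3x3 conv, 64 filters, ReLU, 2x2 pool
  filters: 64
  kernel_size: 3
  dense1: 128
  dense2: 64
  dropout_rate: 0.5
  n_classes: 2

train:
  batch_size: 64
  epochs: 150
  learning_rate: 0.0001  # Adam initial lr
  lr_decay: 0.000001     # legacy per-update decay: lr / (1 + decay * step)
  seed: 0                # overwritten by the master seed
  checkpoint: val_auc    # keep the best-validation-AUC epoch
  deterministic: true
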