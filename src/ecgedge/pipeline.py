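"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

Each stage exists both as an in-memory function (used by the test-bench
and the reproduction script) and as a disk-backed command (used by the
CLI): records as per-lead CSV, composites as NPY/PNG with a manifest CSV,
the model as a JSON document, predictions and metrics as CSV/JSON.
Per-record preprocessing failures quarantine the record and never abort
the batch.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation
from .cohort import build_splits
from .config import PipelineConfig, save_config, stage_seed
from .imaging import CompositeImage, beat_to_image, image_from_npy, image_to_npy, image_to_png
from .model import (
    NumpyCnn,
    build_model,
    export_json,
    import_json,
    predict_proba,
    train_model,
)
from .preprocess import (
    QualityError,
    apply_missing_filters,
    average_beats,
    detect_r_peaks,
    dominant_beat,
    reject_ectopic,
)
from .records import EcgRecord, read_record_csv
from .synth import SynthCohort, simulate_cohort, write_cohort

log = logging.getLogger("ecgedge")


def preprocess_record(
    record: EcgRecord, cfg: PipelineConfig, with_dominant: bool
) -> dict[str, CompositeImage]:
    """Filters -> R peaks -> ectopic rejection -> averaged (and optionally
    dominant) beat -> composite image(s) for one record."""
    rec = apply_missing_filters(record, cfg.filters)
    peaks = detect_r_peaks(rec)
    accepted = reject_ectopic(rec, peaks)
    out = {"averaged": beat_to_image(average_beats(rec, accepted), cfg.imaging)}
    if with_dominant:
        out["dominant"] = beat_to_image(dominant_beat(rec, accepted), cfg.imaging)
    return out


def cohort_to_images(
    cohort: SynthCohort, cfg: PipelineConfig, with_dominant: bool
) -> tuple[dict[str, dict[str, CompositeImage]], dict[str, int], list[dict]]:
    """Per-patient composite images; failures are collected, not raised."""
    images: dict[str, dict[str, CompositeImage]] = {}
    labels: dict[str, int] = {}
    rejects: list[dict] = []
    for rec in cohort.records:
        try:
            images[rec.patient_id] = preprocess_record(rec, cfg, with_dominant)
            labels[rec.patient_id] = int(rec.label)
        except (QualityError, ValueError) as exc:
            rejects.append({"patient_id": rec.patient_id, "reason": str(exc)})
            log.warning("record %s rejected: %s", rec.patient_id, exc)
    return images, labels, rejects


def _stack(images: list[CompositeImage]) -> np.ndarray:
    return np.stack([im.pixels for im in images]).astype(np.float32)


def assemble_partitions(
    images: dict[str, dict[str, CompositeImage]],
    labels: dict[str, int],
    cfg: PipelineConfig,
):
    """Patient-level class-balanced split; dominant-waveform augmentation
    inside train/val only, test uses the averaged image alone."""
    splits = build_splits(
        sorted(labels.items()), cfg.split_ratios, seed=stage_seed(cfg.seed, "split")
    )
    parts: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for part in ("train", "val", "test"):
        imgs, ys, pids = [], [], []
        for pid in sorted(splits[part]):
            sources = ["averaged"]
            if part in ("train", "val") and cfg.augment and "dominant" in images[pid]:
                sources.append("dominant")
            for src in sources:
                imgs.append(images[pid][src])
                ys.append(labels[pid])
                pids.append(pid)
        parts[part] = (_stack(imgs), np.asarray(ys, dtype=int), pids)
    return parts, splits


def run_end_to_end(cfg: PipelineConfig) -> dict:
    """Full in-memory pipeline on a synthetic cohort; returns the trained
    bundle, its JSON document, held-out scores, and the metrics report."""
    cohort = simulate_cohort(cfg.synth)
    with_dominant = cfg.augment
    images, labels, rejects = cohort_to_images(cohort, cfg, with_dominant)
    parts, splits = assemble_partitions(images, labels, cfg)
    (xtr, ytr, _), (xva, yva, _), (xte, yte, te_pids) = (
        parts["train"],
        parts["val"],
        parts["test"],
    )

    bundle = build_model(cfg.cnn, seed=stage_seed(cfg.seed, "init"))
    bundle, history = train_model(bundle, xtr, ytr, xva, yva, cfg.train)
    doc = export_json(bundle)

    net = NumpyCnn(bundle)
    scores = net.predict_proba(xte)[:, 1]

    # built-in edge-equivalence check on a sample of held-out images
    k = min(20, xte.shape[0])
    edge = predict_proba(doc, xte[:k])[:, 1]
    equiv_err = float(np.max(np.abs(edge - scores[:k]))) if k else 0.0

    cutoff = cfg.cutoff if cfg.cutoff is not None else evaluation.optimize_cutoff(scores, yte)
    report = evaluation.metrics_with_ci(scores, yte, cutoff)
    return {
        "bundle": bundle,
        "doc": doc,
        "history": history,
        "splits": splits,
        "rejects": rejects,
        "test_scores": scores,
        "test_labels": yte,
        "test_patients": te_pids,
        "cutoff": cutoff,
        "report": report,
        "equivalence_max_abs_err": equiv_err,
    }


# -- disk-backed commands -------------------------------------------------

def cmd_simulate(cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir) / "cohort"
    cohort = simulate_cohort(cfg.synth)
    write_cohort(cohort, out)
    save_config(cfg, out / "config.yaml")
    log.info("simulate: %d records -> %s (seed %d, config %s)",
             len(cohort.records), out, cfg.seed, cfg.config_hash())
    return out


def cmd_preprocess(cfg: PipelineConfig) -> Path:
    rec_dir = Path(cfg.records_dir or Path(cfg.output_dir) / "cohort" / "records")
    out = Path(cfg.output_dir) / "images"
    out.mkdir(parents=True, exist_ok=True)
    manifest, rejects = [], []
    for path in sorted(rec_dir.glob("*.csv")):
        try:
            record = read_record_csv(path)
            imgs = preprocess_record(record, cfg, with_dominant=cfg.augment)
            for src, img in imgs.items():
                stem = f"{record.patient_id}_{src}"
                image_to_npy(img, out / f"{stem}.npy")
                image_to_png(img, out / f"{stem}.png")
                manifest.append(
                    {
                        "patient_id": record.patient_id,
                        "image": f"{stem}.npy",
                        "source": src,
                        "label": record.label,
                    }
                )
        except Exception as exc:  # quarantine, never abort the batch
            rejects.append({"record": path.name, "reason": str(exc)})
            log.warning("preprocess: %s rejected: %s", path.name, exc)
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(rejects, columns=["record", "reason"]).to_csv(
        out / "rejects.csv", index=False
    )
    log.info("preprocess: %d images, %d rejects -> %s", len(manifest), len(rejects), out)
    return out


def _load_manifest_images(cfg: PipelineConfig):
    img_dir = Path(cfg.output_dir) / "images"
    manifest = pd.read_csv(img_dir / "manifest.csv")
    images: dict[str, dict[str, CompositeImage]] = {}
    labels: dict[str, int] = {}
    for row in manifest.itertuples():
        images.setdefault(row.patient_id, {})[row.source] = image_from_npy(
            img_dir / row.image, cfg.imaging
        )
        labels[row.patient_id] = int(row.label)
    return images, labels


def cmd_train(cfg: PipelineConfig) -> Path:
    images, labels = _load_manifest_images(cfg)
    parts, splits = assemble_partitions(images, labels, cfg)
    (xtr, ytr, _), (xva, yva, _) = parts["train"], parts["val"]
    bundle = build_model(cfg.cnn, seed=stage_seed(cfg.seed, "init"))
    bundle, history = train_model(bundle, xtr, ytr, xva, yva, cfg.train)
    out = Path(cfg.output_dir)
    (out / "model.json").write_text(json.dumps(export_json(bundle)))
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    (out / "splits.json").write_text(
        json.dumps({k: sorted(v) for k, v in splits.items()}, indent=1)
    )
    log.info(
        "train: best epoch %s (val AUC %s) -> %s",
        bundle.metadata.get("best_epoch"),
        bundle.metadata.get("best_val_auc"),
        out / "model.json",
    )
    return out / "model.json"


def cmd_predict(cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir)
    doc = json.loads((out / "model.json").read_text())
    images, labels = _load_manifest_images(cfg)
    splits = json.loads((out / "splits.json").read_text())
    rows = []
    for pid in sorted(splits["test"]):
        pred = predict_proba(doc, [images[pid]["averaged"]])[0]
        rows.append(
            {
                "patient_id": pid,
                "p_nonaf": float(pred[0]),
                "p_af": float(pred[1]),
                "label": labels[pid],
            }
        )
    path = out / "predictions.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    log.info("predict: %d patients -> %s", len(rows), path)
    return path


def cmd_evaluate(cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir)
    preds = pd.read_csv(out / "predictions.csv")
    scores = preds["p_af"].to_numpy()
    labels = preds["label"].to_numpy(dtype=int)

    # built-in check: independent engine vs trainer forward pass
    doc = json.loads((out / "model.json").read_text())
    images, _ = _load_manifest_images(cfg)
    sample = [images[p]["averaged"] for p in preds["patient_id"][:10]]
    net = NumpyCnn(import_json(doc))
    framework = net.predict_proba(_stack(sample))[:, 1]
    edge = predict_proba(doc, sample)[:, 1]
    equiv = float(np.max(np.abs(framework - edge)))
    if equiv > 1e-5:
        raise RuntimeError(f"edge inference deviates from framework by {equiv:g}")

    cutoff = cfg.cutoff if cfg.cutoff is not None else evaluation.optimize_cutoff(scores, labels)
    report = evaluation.metrics_with_ci(scores, labels, cutoff)
    result = report.to_dict()
    result["edge_equivalence_max_abs_err"] = equiv
    (out / "metrics.json").write_text(json.dumps(result, indent=1))
    evaluation.roc_points(scores, labels).to_csv(out / "roc.csv", index=False)
    log.info("evaluate: cutoff %.3f AUC %.3f -> %s", cutoff, report.auc.estimate, out)
    return out / "metrics.json"
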