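"""End-to-end pipeline: simulate -> train -> predict -> evaluate -> endpoints.

Each stage reads/writes plain files (NIfTI volumes, CSV tables, npz
checkpoints) under the run's output directory and appends to a JSON
manifest recording inputs, outputs, seeds and checksums, so a run is
auditable and repeatable from its persisted config alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, save_config, substream
from .endpoints import ancova_arm_test, percent_tlv_change
from .inference import ensemble
from .lesion_metrics import cohort_correlations, evaluate_scan
from .network import load_checkpoint, save_checkpoint
from .phantom import generate_cohort, generate_subject
from .preprocess import extract_training_patches, normalize, plan_patches
from .training import split_folds, train_fold
from .volume_io import CHANNEL_ORDER, MultimodalVolume, read_volume, \
    write_volume

__all__ = ["run_pipeline", "simulate_stage", "train_stage", "predict_stage",
           "evaluate_stage", "endpoints_stage"]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.path = out_dir / "manifest.json"
        self.doc = {"seed": config.seed, "stages": [], "status": "running"}

    def record(self, stage: str, outputs: list[Path], **info):
        self.doc["stages"].append({
            "stage": stage,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": [{"path": str(p), "sha256_16": _checksum(p)}
                        for p in outputs],
            **info,
        })
        self._flush()

    def fail(self, stage: str, err: Exception):
        self.doc["status"] = f"failed at {stage}: {err}"
        self._flush()

    def finish(self):
        self.doc["status"] = "complete"
        self._flush()

    def _flush(self):
        self.path.write_text(json.dumps(self.doc, indent=2))


def simulate_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    rng = substream(config.seed, "phantom")
    sim_dir = out_dir / "subjects"
    sim_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for i in range(config.n_subjects):
        vol, mask = generate_subject(config.phantom, seed=rng)
        for name in CHANNEL_ORDER:
            p = sim_dir / f"sub{i:03d}_{name}.nii.gz"
            write_volume(p, vol.grid, vol.channels[name])
            outputs.append(p)
        p = sim_dir / f"sub{i:03d}_mask.nii.gz"
        write_volume(p, mask.grid, mask.labels)
        outputs.append(p)
    visits, patients = generate_cohort(config.cohort,
                                       seed=substream(config.seed, "cohort"))
    vpath = out_dir / "cohort_visits.csv"
    ppath = out_dir / "cohort_patients.csv"
    visits.to_csv(vpath, index=False)
    patients.to_csv(ppath, index=False)
    outputs += [vpath, ppath]
    return outputs


def _load_subject(sim_dir: Path, i: int):
    channels = {}
    grid = None
    for name in CHANNEL_ORDER:
        grid, data = read_volume(sim_dir / f"sub{i:03d}_{name}.nii.gz")
        channels[name] = data
    vol = MultimodalVolume(grid, channels)
    mask = read_volume(sim_dir / f"sub{i:03d}_mask.nii.gz", "mask")
    return vol, mask


def _subject_patches(config: RunConfig, out_dir: Path, ids):
    plan = plan_patches(config.phantom.grid, config.eval.patch_shape,
                        config.eval.overlap_fraction)
    patches = []
    for i in ids:
        vol, mask = _load_subject(out_dir / "subjects", i)
        patches.extend(extract_training_patches(normalize(vol), mask, plan))
    return patches


def train_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    ids = [f"{i:03d}" for i in range(config.n_subjects)]
    folds = split_folds(ids, k=config.eval.n_folds,
                        seed=config.seed)
    outputs = []
    for fold in range(folds.k):
        val_ids = [int(p) for p in folds.fold_patients(fold)]
        train_ids = [int(p) for p, f in folds.assignments.items()
                     if f != fold]
        train_p = _subject_patches(config, out_dir, train_ids)
        val_p = _subject_patches(config, out_dir, val_ids)
        handle, history = train_fold(train_p, val_p, config.train)
        ck = out_dir / f"fold{fold}.npz"
        save_checkpoint(ck, handle, extra={"fold": fold})
        pd.DataFrame(history).to_csv(out_dir / f"fold{fold}_history.tsv",
                                     sep="\t", index=False)
        outputs += [ck, out_dir / f"fold{fold}_history.tsv"]
    return outputs


def predict_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    handles = [load_checkpoint(p)
               for p in sorted(out_dir.glob("fold*.npz"))]
    if not handles:
        raise FileNotFoundError("no fold checkpoints found; run train first")
    pred_dir = out_dir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    plan = plan_patches(config.phantom.grid, config.eval.patch_shape,
                        config.eval.overlap_fraction)
    outputs = []
    for i in range(config.n_subjects):
        vol, _ = _load_subject(out_dir / "subjects", i)
        pred = ensemble(handles, normalize(vol), n_mc=config.eval.n_mc,
                        seed=config.seed, threshold=config.eval.threshold,
                        plan=plan)
        for suffix, arr in (("prob", pred.mean_prob.probs),
                            ("uncertainty", pred.uncertainty),
                            ("mask", pred.mask.labels)):
            p = pred_dir / f"sub{i:03d}_{suffix}.nii.gz"
            write_volume(p, vol.grid, arr)
            outputs.append(p)
    return outputs


def evaluate_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    rows = []
    reports = []
    for i in range(config.n_subjects):
        gt = read_volume(out_dir / "subjects" / f"sub{i:03d}_mask.nii.gz",
                         "mask")
        pred = read_volume(
            out_dir / "predictions" / f"sub{i:03d}_mask.nii.gz", "mask")
        rep = evaluate_scan(gt, pred,
                            min_size=config.eval.min_lesion_voxels,
                            threshold=config.eval.detection_overlap)
        reports.append(rep)
        rows.append({"subject": i, **asdict(rep)})
    per_scan = pd.DataFrame(rows)
    csv_path = out_dir / "evaluation.csv"
    per_scan.to_csv(csv_path, index=False)
    summary = {c: float(np.nanmean(per_scan[c]))
               for c in ("dc", "ppv", "tpr", "ltpr", "lppv", "lfpr")}
    if len(reports) >= 3:
        r_vol, r_count = cohort_correlations(reports)
        summary["r_vol"] = r_vol
        summary["r_count"] = r_count
    json_path = out_dir / "evaluation_summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return [csv_path, json_path]


def endpoints_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    visits = pd.read_csv(out_dir / "cohort_visits.csv")
    patients = pd.read_csv(out_dir / "cohort_patients.csv")
    change = percent_tlv_change(visits)
    anc = ancova_arm_test(visits, patients)
    cpath = out_dir / "tlv_change.csv"
    change.to_csv(cpath, index=False)
    apath = out_dir / "ancova.json"
    apath.write_text(json.dumps({
        "arm_effect": anc.arm_effect, "p_value": anc.p_value, "n": anc.n,
        "dropped_covariates": anc.dropped_covariates}, indent=2))
    return [cpath, apath]


_STAGES = {
    "simulate": simulate_stage,
    "train": train_stage,
    "predict": predict_stage,
    "evaluate": evaluate_stage,
    "endpoints": endpoints_stage,
}


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the requested stages in order; returns the manifest dict.

    Any stage failure is recorded in the manifest (partial outputs are
    retained) and re-raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "run_config.yaml")
    manifest = _Manifest(out_dir, config)
    stages = list(stages or _STAGES)
    for name in stages:
        fn = _STAGES[name]
        try:
            outputs = fn(config, out_dir)
        except Exception as err:
            manifest.fail(name, err)
            raise
        manifest.record(name, outputs)
    manifest.finish()
    return manifest.doc
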