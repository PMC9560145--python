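"""Top-level pipeline: simulate -> train -> predict -> count -> compare.

Each stage reads the previous stage's on-disk artifacts and writes its own
under ``<output_root>/<stage>/`` together with a provenance sidecar (config
hash, seed, stage).  Stages may be skipped as long as what a requested stage
needs is already on disk — e.g. ``simulate`` + ``count`` counts the
ground-truth label volumes directly, bypassing the model entirely.
"""

from __future__ import annotations

import glob
import json
import logging
import os

import numpy as np
import pandas as pd

from . import compare as cmp_mod
from . import io as vio
from .config import RunConfig, provenance_sidecar
from .phantom import generate_dataset
from .postprocess import CountRecord, count_from_probabilities, count_instances
from .segmentation import build_model, load_checkpoint, predict_volume, save_checkpoint, train

log = logging.getLogger("cocoonct")

STAGES = ("simulate", "train", "predict", "count", "compare")


def run_pipeline(config: RunConfig, stages: list[str]) -> dict[str, str]:
    """Run the requested stages in pipeline order; returns stage -> out dir."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages are {list(STAGES)}")
    ordered = [s for s in STAGES if s in stages]
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("run config hash=%s seed=%d stages=%s", config.hash(), config.seed, ordered)
    log.info("resolved config: %s", json.dumps(config.to_dict(), sort_keys=True))
    out = {}
    for stage in ordered:
        out[stage] = _STAGE_FNS[stage](config)
    return out


def _stage_dir(config: RunConfig, stage: str) -> str:
    d = os.path.join(config.output_root, stage)
    os.makedirs(d, exist_ok=True)
    return d


def _require(path: str, stage: str, needed_by: str) -> None:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage '{needed_by}' needs '{path}' from stage '{stage}'; run it first")


def _run_simulate(config: RunConfig) -> str:
    d = _stage_dir(config, "simulate")
    generate_dataset(config.phantom, d, n_volumes=config.n_volumes, seed=config.seed,
                     count_range=config.count_range, n_val=config.n_val)
    provenance_sidecar(os.path.join(d, "provenance.json"), config, "simulate")
    return d


def _load_pairs(sim_dir: str, ids: list[str]):
    pairs = []
    for vid in ids:
        img, _ = vio.read_volume(os.path.join(sim_dir, f"image_{vid}.nii.gz"))
        lab, _ = vio.read_volume(os.path.join(sim_dir, f"labels_{vid}.nii.gz"))
        pairs.append((img.astype(np.float32), lab.astype(np.uint8)))
    return pairs


def _run_train(config: RunConfig) -> str:
    sim = os.path.join(config.output_root, "simulate")
    _require(os.path.join(sim, "dataset.json"), "simulate", "train")
    with open(os.path.join(sim, "dataset.json")) as fh:
        split = json.load(fh)
    train_pairs = _load_pairs(sim, split["train"])
    val_pairs = _load_pairs(sim, split["val"])
    model = build_model(config.model, seed=config.seed)
    model, history = train(model, train_pairs, val_pairs, config.training)
    d = _stage_dir(config, "train")
    save_checkpoint(os.path.join(d, "model"), model, config.training)
    with open(os.path.join(d, "history.json"), "w") as fh:
        json.dump(history, fh, indent=1)
    provenance_sidecar(os.path.join(d, "provenance.json"), config, "train")
    return d


def _run_predict(config: RunConfig) -> str:
    sim = os.path.join(config.output_root, "simulate")
    ckpt = os.path.join(config.output_root, "train", "model.npz")
    _require(ckpt, "train", "predict")
    _require(os.path.join(sim, "dataset.json"), "simulate", "predict")
    model = load_checkpoint(ckpt)
    d = _stage_dir(config, "predict")
    for img_path in sorted(glob.glob(os.path.join(sim, "image_*.nii.gz"))):
        vid = os.path.basename(img_path)[len("image_"):-len(".nii.gz")]
        vol, meta = vio.read_volume(img_path)
        probs = predict_volume(model, vol, config.training.clip_window,
                               patch_size=config.training.patch_size)
        vio.write_probability_volume(os.path.join(d, f"probs_{vid}.nii.gz"), probs, meta)
    provenance_sidecar(os.path.join(d, "provenance.json"), config, "predict")
    return d


def _run_count(config: RunConfig) -> str:
    pred = os.path.join(config.output_root, "predict")
    sim = os.path.join(config.output_root, "simulate")
    d = _stage_dir(config, "count")
    records = []
    prob_files = sorted(glob.glob(os.path.join(pred, "probs_*.nii.gz")))
    if prob_files:
        for path in prob_files:
            vid = os.path.basename(path)[len("probs_"):-len(".nii.gz")]
            probs, _ = vio.read_probability_volume(path)
            _, _, rec = count_from_probabilities(probs, config.postprocess, sample_id=vid)
            records.append(rec)
    else:
        label_files = sorted(glob.glob(os.path.join(sim, "labels_*.nii.gz")))
        if not label_files:
            _require(os.path.join(sim, "labels_000.nii.gz"), "simulate or predict", "count")
        for path in label_files:
            vid = os.path.basename(path)[len("labels_"):-len(".nii.gz")]
            lab, _ = vio.read_volume(path)
            _, _, rec = count_instances(lab.astype(np.uint8), config.postprocess,
                                        sample_id=vid)
            records.append(rec)
    frame = pd.DataFrame([{
        "sample_id": r.sample_id, "healthy": r.healthy, "parasitoid": r.parasitoid,
        "parasitoid_rate": "" if r.parasitoid_rate_display is None
        else f"{r.parasitoid_rate_display:.2f}",
    } for r in records])
    frame.to_csv(os.path.join(d, "counts.csv"), index=False, lineterminator="\n")
    provenance_sidecar(os.path.join(d, "provenance.json"), config, "count")
    return d


def _run_compare(config: RunConfig) -> str:
    d = _stage_dir(config, "compare")
    counts_csv = os.path.join(config.output_root, "count", "counts.csv")
    sim = os.path.join(config.output_root, "simulate")
    if os.path.exists(counts_csv) and glob.glob(os.path.join(sim, "manifest_*.json")):
        counted = pd.read_csv(counts_csv, dtype={"sample_id": str})
        ac = [CountRecord(sample_id=row["sample_id"], healthy=int(row["healthy"]),
                          parasitoid=int(row["parasitoid"]))
              for _, row in counted.iterrows()]
        vc = []
        for path in sorted(glob.glob(os.path.join(sim, "manifest_*.json"))):
            with open(path) as fh:
                m = json.load(fh)
            vc.append(CountRecord(sample_id=m["volume_id"], healthy=m["healthy_count"],
                                  parasitoid=m["parasitoid_count"]))
        table = cmp_mod.build_table({"AC": ac, "VC": vc})
        pairs = [("AC", "VC")]
    else:
        table = cmp_mod.load_reference_counts()
        pairs = [("RC", "VC")]
    reports = cmp_mod.normality_screen(
        {f"{m} healthy": table.column(m, "healthy") for m in table.methods})
    for pair in pairs:
        for variable in ("healthy", "parasitoid", "rate"):
            try:
                reports.append(cmp_mod.compare_methods(table, pair, variable))
            except ValueError as exc:  # undefined rates in tiny synthetic batches
                log.warning("skipping %s on %s: %s", variable, pair, exc)
    text = cmp_mod.render_report(table, reports, out_csv=os.path.join(d, "report.csv"))
    with open(os.path.join(d, "report.txt"), "w") as fh:
        fh.write(text)
    provenance_sidecar(os.path.join(d, "provenance.json"), config, "compare")
    return d


_STAGE_FNS = {"simulate": _run_simulate, "train": _run_train, "predict": _run_predict,
              "count": _run_count, "compare": _run_compare}
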