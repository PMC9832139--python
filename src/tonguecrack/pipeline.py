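"""End-to-end orchestration: split, train, predict, evaluate, quantify.

``run_pipeline`` chains every stage of the tongue-crack workflow on
synthetic data — generate, stratified 8:2 split, augment training
positives, train the segmentation then the decision network, post-process
predictions on the held-out images, and report segmentation metrics,
classification metrics and the two TCM crack indices — writing all
artifacts plus a JSON-lines run log that records the seed of every
stochastic stage.
"""

from __future__ import annotations

import json
import os
import time

import numpy as np
import pandas as pd
import yaml

from .augment import DEFAULT_GAMMA, DEFAULT_SP_FRACTION, expand_positives
from .crack_indices import IndexConfig, compute_fdi, compute_fci
from .evalmetrics import BinaryCounts, ConfusionCounts, cls_metrics, confusion, seg_metrics
from .postprocess import postprocess_pipeline
from .sbdl import dec_forward, save_checkpoint, seg_forward
from .synthdata import CRACKED, SynthConfig, generate_dataset
from .training import TrainConfig, train_decnet, train_segnet
from . import nn

__all__ = ["split_dataset", "classify_image", "evaluate_model", "run_pipeline", "DEFAULT_CONFIG"]


def split_dataset(samples, ratio: float, seed: int):
    """Per-class stratified split into (train, test).

    The train side of each class gets round-half-up(ratio * class size)
    samples — the rule that sends 176 positives to 141/35 and 140
    negatives to 112/28 at ratio 0.8.  Shuffling is seeded; an empty class
    is an error.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    by_label = {}
    for s in samples:
        by_label.setdefault(s.label, []).append(s)
    if len(by_label) < 2:
        raise ValueError(
            f"stratified split needs both classes, got only {sorted(by_label)}"
        )
    rng = np.random.default_rng(int(seed))
    train, test = [], []
    for label in sorted(by_label):
        group = by_label[label]
        n_train = int(np.floor(ratio * len(group) + 0.5))
        order = rng.permutation(len(group))
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    return train, test


def classify_image(image, seg, dec, threshold: float = 0.5):
    """Full inference for one image.

    Returns ``(probability, mask, skeleton, seg_out)``: the crack
    probability from the decision network and the post-processed
    full-resolution mask and skeleton.
    """
    seg_out = seg_forward(image, seg)
    logit = dec_forward(seg_out, dec)
    prob = float(nn.sigmoid(np.array([logit]))[0])
    mask, skeleton = postprocess_pipeline(seg_out.logit_map, threshold=threshold)
    return prob, mask, skeleton, seg_out


def evaluate_model(samples, seg, dec, threshold: float = 0.5,
                   index_config: IndexConfig = IndexConfig()):
    """Evaluate on labelled samples; returns (metrics dict, per-image table).

    Pixel metrics accumulate confusion counts over all samples that carry a
    ground-truth mask (at full upsampled resolution, against the eroded
    mask); decision metrics count image-level calls at probability 0.5.
    """
    counts = ConfusionCounts.zeros(2)
    y_true, y_pred = [], []
    rows = []
    for i, sample in enumerate(samples):
        prob, mask, skeleton, _ = classify_image(sample.image, seg, dec, threshold)
        predicted = prob > 0.5
        y_true.append(sample.label == CRACKED)
        y_pred.append(predicted)
        if sample.mask is not None:
            counts = counts + confusion(sample.mask, mask)
        fci = compute_fci(mask, config=index_config)
        fdi = compute_fdi(sample.image, mask, config=index_config)
        rows.append(
            {
                "sample": i,
                "label": sample.label,
                "predicted": CRACKED if predicted else "non-cracked",
                "probability": prob,
                "FCI": fci,
                "FDI": fdi,
                "skeleton_px": int(skeleton.sum()),
            }
        )
    metrics = {}
    if counts.total > 0:
        metrics.update(seg_metrics(counts))
    metrics.update(cls_metrics(BinaryCounts.from_pairs(y_true, y_pred)))
    return metrics, pd.DataFrame(rows), counts


#: Demo-scale defaults: small images and short training so a full run
#: finishes in minutes on one CPU.  Override any entry via the config file.
DEFAULT_CONFIG = {
    "synth": {
        "n_pos": 16,
        "n_neg": 16,
        "image_size": 64,
        "n_cracks": [1, 3],
        "width_range": [1, 4],
        "contrast_gap": 60,
        "papillae_density": 15,
        "contour_ring": True,
        "seed": 0,
    },
    "split": {"ratio": 0.8, "seed": 0},
    "augment": {
        "enabled": True,
        "sp_fraction": DEFAULT_SP_FRACTION,
        "gamma": DEFAULT_GAMMA,
        "seed": 0,
    },
    "train": {
        "learning_rate": 0.005,
        "loss_weight": 0.1,
        "batch_size": 2,
        "epochs_seg": 100,
        "epochs_dec": 100,
        "seed": 0,
        "loss": "bce",
    },
    "predict": {"threshold": 0.5},
    "indices": {"k_v": 10.0, "k_d": 2.0},
}


def _merge(base, override):
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(config):
    """Accept a dict, a YAML/JSON path, or None (defaults)."""
    if config is None:
        return dict(DEFAULT_CONFIG)
    if isinstance(config, dict):
        return _merge(DEFAULT_CONFIG, config)
    with open(config) as fh:
        loaded = yaml.safe_load(fh)
    return _merge(DEFAULT_CONFIG, loaded or {})


def run_pipeline(config=None, out_dir="run"):
    """Execute synth -> split -> augment -> train -> predict -> evaluate.

    Writes images, checkpoint, ``report.csv`` (all eight metrics, percent),
    ``indices.csv`` and ``run_log.jsonl`` under ``out_dir``; returns the
    metrics dict.  Any stage failure aborts with the stage name.
    """
    cfg = load_config(config)
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run_log.jsonl")
    log_fh = open(log_path, "a")


    def stage(name, seed, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            log_fh.write(json.dumps({"stage": name, "status": "failed", "error": str(exc)}) + "\n")
            log_fh.close()
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        log_fh.write(
            json.dumps(
                {
                    "stage": name,
                    "status": "ok",
                    "seed": seed,
                    "elapsed_s": round(time.perf_counter() - t0, 3),
                }
            )
            + "\n"
        )
        log_fh.flush()
        return result

    def _synth():
        sc = cfg["synth"]
        synth_cfg = SynthConfig(
            image_size=sc["image_size"],
            n_cracks=tuple(sc["n_cracks"]),
            width_range=tuple(sc["width_range"]),
            contrast_gap=sc["contrast_gap"],
            papillae_density=sc["papillae_density"],
            contour_ring=sc["contour_ring"],
            seed=sc["seed"],
        )
        return generate_dataset(sc["n_pos"], sc["n_neg"], synth_cfg, sc["seed"])

    samples = stage("synth", cfg["synth"]["seed"], _synth)
    train, test = stage(
        "split",
        cfg["split"]["seed"],
        lambda: split_dataset(samples, cfg["split"]["ratio"], cfg["split"]["seed"]),
    )

    def _augment():
        ac = cfg["augment"]
        if not ac.get("enabled", True):
            return train
        pos = [s for s in train if s.label == CRACKED]
        neg = [s for s in train if s.label != CRACKED]
        return expand_positives(pos, ac["seed"], ac["sp_fraction"], ac["gamma"]) + neg

    train_aug = stage("augment", cfg["augment"]["seed"], _augment)

    tc = cfg["train"]
    train_cfg = TrainConfig(
        learning_rate=tc["learning_rate"],
        loss_weight=tc["loss_weight"],
        batch_size=tc["batch_size"],
        epochs_seg=tc["epochs_seg"],
        epochs_dec=tc["epochs_dec"],
        seed=tc["seed"],
        loss=tc.get("loss", "bce"),
    )
    seg = stage("train_seg", tc["seed"], lambda: train_segnet(train_aug, train_cfg))
    dec = stage("train_dec", tc["seed"], lambda: train_decnet(train_aug, seg, train_cfg))
    stage(
        "checkpoint",
        tc["seed"],
        lambda: save_checkpoint(os.path.join(out_dir, "checkpoint"), seg, dec, cfg["train"]),
    )

    ic = cfg["indices"]
    index_cfg = IndexConfig(k_v=ic["k_v"], k_d=ic["k_d"])

    def _evaluate():
        return evaluate_model(
            test, seg, dec, threshold=cfg["predict"]["threshold"], index_config=index_cfg
        )

    metrics, table, _ = stage("evaluate", tc["seed"], _evaluate)

    report = pd.DataFrame(
        {
            "metric": list(metrics),
            "value_percent": [round(100.0 * metrics[k], 1) for k in metrics],
        }
    )
    report.to_csv(os.path.join(out_dir, "report.csv"), index=False)
    table.to_csv(os.path.join(out_dir, "indices.csv"), index=False)
    log_fh.write(json.dumps({"stage": "report", "status": "ok", "metrics": {k: (None if v != v else v) for k, v in metrics.items()}}) + "\n")
    log_fh.close()
    return metrics
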