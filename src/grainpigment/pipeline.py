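"""End-to-end pipeline: generate -> split -> segment -> features/train ->
predict -> evaluate, from one declarative config.

Every stochastic stage derives its seed from the global seed plus the stage
name (stable hash), so a run is a pure function of its config.  A run
manifest (``run.json``) records the config hash and per-stage wall times,
making every artifact in the run directory traceable to its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import imageio.v3 as iio
import joblib
import numpy as np
import pandas as pd
import yaml

from .classifiers import (
    CNNPigmentClassifier,
    MultiTaskClassifier,
    RF13Classifier,
    TwoChannelClassifier,
)
from .evaluation import EvalReport, compute_acc
from .features import DescriptorExtractor
from .labels import PigmentLabel
from .manifest import DatasetManifest, stratified_split
from .segmentation import GrainSegmenter, crop_grain_region, load_pairs
from .synthetic import RenderConfig, generate_dataset

__all__ = ["DEFAULT_CONFIG", "load_config", "stage_seed", "run_pipeline",
           "save_model", "load_model"]

log = logging.getLogger("grainpigment")

MODEL_KINDS = ("rf13", "cnn", "unet_classhead", "unet_classsegment")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "runs/demo",
    "generator": {
        "classes": {"NP": 4, "A": 4, "M": 4, "AM": 4},
        "hulled_fraction": 0.5,
        "replicates": 3,
        "image_size": 96,
        "hard_mode": False,
    },
    "split": {"fractions": [0.6, 0.2, 0.2]},
    "segmenter": {
        # "ground_truth" uses the generator's masks (no network training);
        # "trained" trains the U-Net segmenter on the train split
        "source": "ground_truth",
        "input_size": 96,
        "epochs": 5,
        "base_width": 8,
    },
    "classifier": {"model_kind": "rf13"},
    "evaluation": {"split": "test"},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and stage name."""
    import zlib

    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def save_model(model, path, config: dict | None = None) -> None:
    """Checkpoint a fitted model with its originating config embedded."""
    joblib.dump({"model": model, "config": config or {}}, path)


def load_model(path):
    bundle = joblib.load(path)
    return bundle["model"]


class _StageTimer:
    def __init__(self, run_record: list, name: str, seed: int | None):
        self.run_record, self.name, self.seed = run_record, name, seed

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage=%s seed=%s start", self.name, self.seed)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage=%s failed after %.1fs: %s", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        self.run_record.append({"stage": self.name, "seed": self.seed, "seconds": round(dt, 3)})
        log.info("stage=%s seed=%s done in %.1fs", self.name, self.seed, dt)
        return False


def _masks_for(manifest: DatasetManifest, segmenter: GrainSegmenter | None,
               images: list) -> list:
    if segmenter is None:
        return [(iio.imread(rec.mask_path) > 127).astype(np.uint8) for rec in manifest.records]
    return segmenter.predict(images)


def run_pipeline(config: dict) -> dict:
    """Execute the full pipeline described by ``config``.

    Returns a dict with the run directory, the split manifest, the fitted
    model, the prediction table, and the evaluation report.  Any stage
    failure aborts with the stage name and cause.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val

    kind = cfg["classifier"].get("model_kind", "rf13")
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {kind!r}; expected one of {MODEL_KINDS}")
    seed = int(cfg["seed"])
    run_dir = Path(cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    record: list[dict] = []

    gen_cfg = cfg["generator"]
    with _StageTimer(record, "generate", stage_seed(seed, "generate")):
        render = RenderConfig(
            image_size=int(gen_cfg.get("image_size", 96)),
            replicates_per_accession=int(gen_cfg.get("replicates", 3)),
            hard_mode=bool(gen_cfg.get("hard_mode", False)),
        )
        manifest = generate_dataset(
            dict(gen_cfg["classes"]), render, stage_seed(seed, "generate"),
            run_dir / "data", hulled_fraction=float(gen_cfg.get("hulled_fraction", 0.5)),
        )

    with _StageTimer(record, "split", stage_seed(seed, "split")):
        manifest = stratified_split(
            manifest, tuple(cfg["split"]["fractions"]), stage_seed(seed, "split")
        )
        manifest.save(run_dir / "manifest.csv")

    train_m = manifest.subset("train")
    test_m = manifest.subset(cfg["evaluation"].get("split", "test"))
    val_m = manifest.subset("val")
    train_images, train_masks = load_pairs(train_m)
    test_images, test_masks_gt = load_pairs(test_m)
    train_labels = [r.pigment_label for r in train_m.records]
    test_labels = [r.pigment_label for r in test_m.records]

    segmenter = None
    needs_separate_segmentation = kind in ("rf13", "cnn")
    if needs_separate_segmentation and cfg["segmenter"].get("source") == "trained":
        with _StageTimer(record, "train_seg", stage_seed(seed, "train_seg")):
            seg_cfg = cfg["segmenter"]
            segmenter = GrainSegmenter(
                input_size=int(seg_cfg.get("input_size", 96)),
                epochs=int(seg_cfg.get("epochs", 5)),
                base_width=int(seg_cfg.get("base_width", 8)),
                seed=stage_seed(seed, "train_seg"),
            )
            val_imgs, val_msks = (load_pairs(val_m) if len(val_m) else (None, None))
            segmenter.fit(train_images, train_masks, val_imgs, val_msks)

    cls_cfg = {k: v for k, v in cfg["classifier"].items() if k != "model_kind"}
    cls_seed = stage_seed(seed, "train_cls")
    with _StageTimer(record, "train_cls", cls_seed):
        if kind == "rf13":
            extractor = DescriptorExtractor()
            seg_masks = _masks_for(train_m, segmenter, train_images)
            X_train = extractor.extract_batch(
                train_images, seg_masks, index=[r.image_path for r in train_m.records]
            )
            X_train.to_csv(run_dir / "features_train.csv")
            model = RF13Classifier(seed=cls_seed, **cls_cfg).fit(X_train, train_labels)
        elif kind == "cnn":
            seg_masks = _masks_for(train_m, segmenter, train_images)
            crops = [crop_grain_region(im, mk, padding=2)
                     for im, mk in zip(train_images, seg_masks)]
            model = CNNPigmentClassifier(seed=cls_seed, **cls_cfg).fit(crops, train_labels)
        elif kind == "unet_classhead":
            model = MultiTaskClassifier(seed=cls_seed, **cls_cfg).fit(
                train_images, train_masks, train_labels
            )
        else:  # unet_classsegment
            model = TwoChannelClassifier(seed=cls_seed, **cls_cfg).fit(
                train_images, train_masks, train_labels
            )
        save_model(model, run_dir / "model.joblib", cfg)

    with _StageTimer(record, "predict", None):
        if kind == "rf13":
            extractor = DescriptorExtractor()
            seg_masks = _masks_for(test_m, segmenter, test_images)
            X_test = extractor.extract_batch(
                test_images, seg_masks, index=[r.image_path for r in test_m.records]
            )
            preds = model.predict(X_test)
            proba = model.forest_.predict_proba(model.transform(X_test))
            classes = list(model.forest_.classes_)
            p_a = proba[:, [classes.index(c) for c in ("A", "AM") if c in classes]].sum(axis=1)
            p_m = proba[:, [classes.index(c) for c in ("M", "AM") if c in classes]].sum(axis=1)
            scores = np.stack([p_a, p_m], axis=1)
        elif kind == "cnn":
            seg_masks = _masks_for(test_m, segmenter, test_images)
            crops = [crop_grain_region(im, mk, padding=2)
                     for im, mk in zip(test_images, seg_masks)]
            scores = model.predict_scores(crops)
            preds = model.predict(crops)
        elif kind == "unet_classhead":
            scores = model.predict_scores(test_images)
            preds = model.predict(test_images)
        else:
            preds = model.predict(test_images)
            scores = np.array([[float(p.anthocyanin), float(p.melanin)] for p in preds])
        pred_table = pd.DataFrame(
            {
                "image_path": [r.image_path for r in test_m.records],
                "p_anthocyanin": scores[:, 0],
                "p_melanin": scores[:, 1],
                "predicted_label": [p.code for p in preds],
                "true_label": [t.code for t in test_labels],
                "hulled": [r.hulled for r in test_m.records],
            }
        )
        pred_table.to_csv(run_dir / "predictions.csv", index=False)

    with _StageTimer(record, "evaluate", None):
        report = compute_acc(preds, test_labels, hulled=[r.hulled for r in test_m.records])
        report.to_json(run_dir / "report.json")

    with open(run_dir / "run.json", "w") as fh:
        json.dump({"config": cfg, "config_hash": config_hash(cfg), "stages": record}, fh, indent=2)

    return {
        "run_dir": run_dir,
        "manifest": manifest,
        "model": model,
        "predictions": pred_table,
        "report": report,
    }
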