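"""End-to-end run: data -> segment -> features -> fuse -> train -> evaluate.

Every stage seed is derived from the single config seed by a fixed offset,
so the whole run — including the generated data, the backbone fine-tune and
the head training — is a pure function of the configuration.  The report
JSON is written with sorted keys and no timestamps, making reruns
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import backbone as bb
from .evaluation import TrainConfig, evaluate, train_head
from .fusion import fit_standardizer, fuse
from .heads import HeadConfig, build_head
from .io import FeatureTable, PipelineConfig, load_image_dataset, read_image, \
    write_feature_table
from .segmentation import segment_leaf
from .shallow import ShallowConfig, extract_shallow
from .synthetic import default_recipes, generate_dataset, stratified_split

log = logging.getLogger("leaffuse")

__all__ = ["run_pipeline"]

# fixed per-stage seed offsets
_SEED_DATA, _SEED_BACKBONE, _SEED_FINETUNE, _SEED_HEAD, _SEED_TRAIN = 0, 1, 2, 3, 4


def _stage(name, t0):
    log.info("stage %-16s %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig):
    """Execute the full diagnosis pipeline; returns (report, artifacts)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seed = config.seed

    # -- data -----------------------------------------------------------------
    t0 = time.perf_counter()
    if config.data_dir is not None:
        records = load_image_dataset(config.data_dir)
        images = [read_image(r.path) for r in records]
        labels_str = [r.label for r in records]
        ids = [str(r.path) for r in records]
        split = stratified_split(labels_str, seed=seed + _SEED_DATA)
    else:
        samples = generate_dataset(default_recipes(),
                                   n_per_class=config.n_per_class,
                                   size=config.image_size,
                                   seed=seed + _SEED_DATA)
        images = [s.image for s in samples]
        labels_str = [s.label for s in samples]
        ids = [s.sample_id for s in samples]
        split = np.array([s.split for s in samples])
    class_names = config.class_names or sorted(set(labels_str))
    y = np.array([class_names.index(lab) for lab in labels_str])
    _stage("data", t0)

    # -- segmentation + shallow features --------------------------------------
    t0 = time.perf_counter()
    seg = config.segmentation
    scfg = ShallowConfig(bins_per_channel=config.shallow["bins_per_channel"],
                         levels=config.shallow["levels"],
                         distance=config.shallow["distance"])
    shallow = np.empty((len(images), 768 + 24))
    for i, img in enumerate(images):
        mask = segment_leaf(img, polarity=seg["polarity"], tol=seg["tol"],
                            max_iter=seg["max_iter"])
        shallow[i] = extract_shallow(img, mask, scfg)
    _stage("shallow", t0)

    # -- depth features -------------------------------------------------------
    t0 = time.perf_counter()
    bcfg = config.backbone
    if bcfg["name"] == "tiny":
        model = bb.build_tiny_backbone(feature_dim=bcfg["feature_dim"],
                                       n_classes=len(class_names),
                                       seed=seed + _SEED_BACKBONE,
                                       input_size=bcfg["input_size"])
    elif bcfg["name"] == "convnext-base":
        model = bb.build_convnext_base(n_classes=len(class_names),
                                       seed=seed + _SEED_BACKBONE)
    else:
        raise ValueError(f"unknown backbone {bcfg['name']!r}")
    if bcfg["finetune_epochs"] > 0:
        tr = split == "train"
        x_tr = bb.preprocess_images([im for im, t in zip(images, tr) if t],
                                    getattr(model, "input_size", 224))
        ft_cfg = TrainConfig(epochs=bcfg["finetune_epochs"],
                             seed=seed + _SEED_FINETUNE,
                             lr_switch_epoch=max(1, bcfg["finetune_epochs"] // 2))
        bb.finetune_backbone(model, x_tr, y[tr], config=ft_cfg,
                             preprocessed=True)
    depth = bb.extract_depth(model, images)
    _stage("depth", t0)

    # -- fusion ---------------------------------------------------------------
    t0 = time.perf_counter()
    fused_raw = np.concatenate([shallow, depth], axis=1)
    if config.fusion["standardize"]:
        std = fit_standardizer(fused_raw[split == "train"],
                               split=split[split == "train"])
        std.to_json(out / "standardizer.json")
        fused = std.transform(fused_raw)
    else:
        std, fused = None, fused_raw
    table = FeatureTable(ids, labels_str, list(split), fused,
                         blocks={"shallow": shallow.shape[1],
                                 "depth": depth.shape[1]})
    write_feature_table(out / "fused.csv", table)
    _stage("fusion", t0)

    # -- head training + evaluation -------------------------------------------
    t0 = time.perf_counter()
    hcfg = HeadConfig(input_dim=fused.shape[1], n_classes=len(class_names),
                      seed=seed + _SEED_HEAD,
                      **{k: v for k, v in config.head.items()})
    head = build_head(hcfg)
    tcfg = TrainConfig(seed=seed + _SEED_TRAIN, **config.training)
    head, history = train_head(head, fused, y, split=split, config=tcfg)
    te = split == "test"
    report = evaluate(head, fused[te], y[te], class_names=class_names)
    _stage("train+eval", t0)

    report_dict = report.to_dict()
    report_dict["seed"] = seed
    report_dict["n_samples"] = {"train": int((split == "train").sum()),
                                "val": int((split == "val").sum()),
                                "test": int(te.sum())}
    with open(out / "report.json", "w") as fh:
        json.dump(report_dict, fh, sort_keys=True, indent=1)
    artifacts = {"head": head, "backbone": model, "standardizer": std,
                 "history": history, "features": table, "split": split,
                 "labels": y, "class_names": class_names}
    return report, artifacts
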