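"""Dataset loading, feature tables, and pipeline configuration.

Feature tables are plain CSV: columns ``path,label,split,f0..fN-1``, with a
leading comment line declaring block boundaries, e.g.::

    # blocks: shallow=792,depth=32
    path,label,split,f0,f1,...

Values are written with 17 significant digits so a write -> read round trip
reproduces every float bit-exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "ImageRecord", "FeatureTable", "PipelineConfig",
    "load_image_dataset", "read_image", "write_mask",
    "read_feature_table", "write_feature_table",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ImageRecord:
    path: Path
    label: str


def load_image_dataset(root_dir) -> list[ImageRecord]:
    """One subdirectory per class; deterministic lexicographic ordering."""
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records: list[ImageRecord] = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        files = []
        for f in sorted(class_dir.iterdir()):
            if f.suffix.lower() in IMAGE_EXTENSIONS:
                if not f.stem.startswith("mask"):
                    files.append(f)
            elif f.is_file():
                warnings.warn(f"skipping non-image file {f}", stacklevel=2)
        if not files:
            raise ValueError(f"class directory {class_dir.name!r} contains "
                             f"no images")
        records.extend(ImageRecord(f, class_dir.name) for f in files)
    return records


def read_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_mask(path, mask: np.ndarray):
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)
                    ).save(path)


@dataclass
class FeatureTable:
    paths: list[str]
    labels: list[str]
    split: list[str]
    features: np.ndarray            # (n, d) float64
    blocks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        n = self.features.shape[0]
        if not (len(self.paths) == len(self.labels) == len(self.split) == n):
            raise ValueError("column lengths disagree")
        if self.blocks and sum(self.blocks.values()) != self.features.shape[1]:
            raise ValueError("block dims do not sum to feature width")

    def block(self, name: str) -> np.ndarray:
        start = 0
        for bname, dim in self.blocks.items():
            if bname == name:
                return self.features[:, start:start + dim]
            start += dim
        raise KeyError(name)


def write_feature_table(path, table: FeatureTable):
    n, d = table.features.shape
    cols = {"path": table.paths, "label": table.labels, "split": table.split}
    df = pd.DataFrame(cols)
    df = pd.concat([df, pd.DataFrame(table.features,
                                     columns=[f"f{i}" for i in range(d)])],
                   axis=1)
    with open(path, "w") as fh:
        if table.blocks:
            spec = ",".join(f"{k}={v}" for k, v in table.blocks.items())
            fh.write(f"# blocks: {spec}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    blocks: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# blocks:"):
            for part in first.split(":", 1)[1].strip().split(","):
                k, v = part.split("=")
                blocks[k.strip()] = int(v)
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    fcols = [c for c in df.columns if c.startswith("f")]
    feats = df[fcols].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(feats).all(axis=1))
    if bad.size:
        raise ValueError(f"row {int(bad[0]) + 1}: feature count does not "
                         f"match header ({len(fcols)} columns declared)")
    return FeatureTable(df["path"].astype(str).tolist(),
                        df["label"].astype(str).tolist(),
                        df["split"].astype(str).tolist(), feats, blocks)


# -- pipeline configuration ---------------------------------------------------

def _strict(cls, d: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class PipelineConfig:
    """Full end-to-end run configuration; round-trips through YAML."""

    out_dir: str = "leaffuse_run"
    seed: int = 0
    data_dir: str | None = None     # None -> synthetic generation
    n_per_class: int = 12
    image_size: int = 64
    class_names: list[str] | None = None
    segmentation: dict = field(default_factory=lambda: {
        "polarity": "auto", "tol": 0.5, "max_iter": 100})
    shallow: dict = field(default_factory=lambda: {
        "bins_per_channel": 256, "levels": 64, "distance": 1})
    backbone: dict = field(default_factory=lambda: {
        "name": "tiny", "feature_dim": 32, "input_size": 64,
        "finetune_epochs": 8})
    fusion: dict = field(default_factory=lambda: {"standardize": True})
    head: dict = field(default_factory=lambda: {
        "head_type": "FA", "d_model": 64, "n_heads": 4, "hidden_dim": 256})
    training: dict = field(default_factory=lambda: {
        "lr_initial": 0.001, "lr_final": 0.0001, "lr_switch_epoch": 75,
        "epochs": 60, "batch_size": 8})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = _strict(cls, d, "pipeline config")
        defaults = cls()
        for sub in ("segmentation", "shallow", "backbone", "fusion",
                    "head", "training"):
            base = dict(getattr(defaults, sub))
            extra = set(getattr(cfg, sub)) - set(base)
            if extra:
                raise ValueError(f"unknown keys in {sub}: {sorted(extra)}")
            base.update(getattr(cfg, sub))
            setattr(cfg, sub, base)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
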