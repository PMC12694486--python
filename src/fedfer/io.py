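"""Readers and writers for the formats the framework touches.

Supported inputs: the public FER2013 CSV dialect (integer 7-class label,
2304 space-separated pixel values, usage column) and class-subfolder image
directories (PNG/JPEG). The 7-class CSV coding is remapped to the package's
four-emotion space (angry<-0, happy<-3, sad<-4, neutral<-6); the remaining
labels are dropped with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .config import (
    CLASS_NAMES,
    ArchitectureConfig,
    FederatedConfig,
    MaskSpec,
    RunConfig,
)
from .data import LabeledImages

logger = logging.getLogger(__name__)

#: FER2013 7-class coding -> package 4-class index (neutral=0 .. angry=3)
FER2013_REMAP = {0: 3, 3: 1, 4: 2, 6: 0}


def read_fer2013_csv(path) -> LabeledImages:
    df = pd.read_csv(path)
    required = {"emotion", "pixels"}
    if not required.issubset(df.columns):
        raise ValueError(f"FER2013 CSV needs columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    images, labels = [], []
    dropped = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        emotion = int(row.emotion)
        if emotion not in FER2013_REMAP:
            dropped += 1
            continue
        pixels = np.asarray(str(row.pixels).split(), dtype=np.float32)
        if pixels.size != 2304:
            raise ValueError(
                f"line {line_no}: expected 2304 pixel values, got {pixels.size}"
            )
        images.append((pixels / 255.0).reshape(48, 48))
        labels.append(FER2013_REMAP[emotion])
    if dropped:
        logger.info("read_fer2013_csv: dropped %d rows outside the 4-class "
                    "label space", dropped)
    return LabeledImages(np.stack(images) if images else
                         np.empty((0, 48, 48), dtype=np.float32),
                         np.array(labels, dtype=np.int64))


def write_fer2013_csv(dataset: LabeledImages, path) -> None:
    """Inverse of :func:`read_fer2013_csv` at 8-bit quantization."""
    inverse = {v: k for k, v in FER2013_REMAP.items()}
    rows = []
    for img, label in zip(dataset.images, dataset.labels):
        px = np.rint(img[..., 0] * 255.0).astype(np.uint8).ravel()
        rows.append({
            "emotion": inverse[int(label)],
            "pixels": " ".join(map(str, px.tolist())),
            "usage": "Training",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_image_folder(path) -> LabeledImages:
    """Class-subfolder layout; folder names match the four emotions
    case-insensitively. Images are converted to grayscale and resized to
    48x48 (bilinear) if needed."""
    root = Path(path)
    name_to_label = {n: i for i, n in enumerate(CLASS_NAMES)}
    images, labels = [], []
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    for sub in subdirs:
        key = sub.name.lower()
        if key == "masks":
            continue
        if key not in name_to_label:
            raise ValueError(
                f"unknown class folder {sub.name!r}; accepted names "
                f"(case-insensitive): {list(CLASS_NAMES)}"
            )
        for file in sorted(sub.iterdir()):
            if file.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            img = Image.open(file).convert("L")
            if img.size != (48, 48):
                img = img.resize((48, 48), Image.BILINEAR)
            images.append(np.asarray(img, dtype=np.float32) / 255.0)
            labels.append(name_to_label[key])
    return LabeledImages(np.stack(images) if images else
                         np.empty((0, 48, 48), dtype=np.float32),
                         np.array(labels, dtype=np.int64))


def write_image_folder(dataset: LabeledImages, path, write_masks: bool = True) -> None:
    """Class-subfolder PNG export plus masks/ directory and a manifest CSV."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    mask_dir = root / "masks"
    if write_masks and dataset.masks is not None:
        mask_dir.mkdir(exist_ok=True)
    manifest = []
    counters = {name: 0 for name in CLASS_NAMES}
    for i in range(len(dataset)):
        name = CLASS_NAMES[int(dataset.labels[i])]
        counters[name] += 1
        sub = root / name
        sub.mkdir(exist_ok=True)
        fname = f"{name}_{counters[name]:05d}.png"
        arr = np.rint(dataset.images[i, ..., 0] * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(sub / fname)
        entry = {"file": f"{name}/{fname}", "label": name}
        if write_masks and dataset.masks is not None:
            mname = f"mask_{name}_{counters[name]:05d}.png"
            Image.fromarray(
                dataset.masks[i].astype(np.uint8) * 255, mode="L"
            ).save(mask_dir / mname)
            entry["mask"] = f"masks/{mname}"
        manifest.append(entry)
    pd.DataFrame(manifest).to_csv(root / "manifest.csv", index=False)


def read_mask_folder(path) -> np.ndarray | None:
    """Ground-truth masks matching a written image folder, via its manifest."""
    root = Path(path)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        return None
    df = pd.read_csv(manifest)
    if "mask" not in df.columns:
        return None
    # manifest rows are grouped by class in write order; re-sort to match
    # read_image_folder's sorted-filename traversal
    df = df.sort_values("file", kind="stable")
    masks = [np.asarray(Image.open(root / m)) > 127 for m in df["mask"]]
    return np.stack(masks)


# ------------------------------------------------------------------ config IO

def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    arch = raw.get("architecture", {})
    fed = raw.get("federated", {})
    mask = raw.get("mask_spec", {})
    return RunConfig(
        architecture=ArchitectureConfig(
            filter_blocks=tuple(arch.get("filter_blocks", (64, 128, 256))),
            dense_units=tuple(arch.get("dense_units", (256, 128))),
            dropout_rate=float(arch.get("dropout_rate", 0.2)),
        ),
        federated=FederatedConfig(**fed) if fed else FederatedConfig(),
        mask_spec=MaskSpec(**mask) if mask else MaskSpec(),
        seeds=tuple(raw.get("seeds", RunConfig.__dataclass_fields__["seeds"].default)),
        log_level=raw.get("log_level", "INFO"),
    )


def save_run_config(config: RunConfig, path) -> None:
    payload = {
        "architecture": {
            "filter_blocks": list(config.architecture.filter_blocks),
            "dense_units": list(config.architecture.dense_units),
            "dropout_rate": config.architecture.dropout_rate,
        },
        "federated": {
            "n_clients": config.federated.n_clients,
            "local_epochs": config.federated.local_epochs,
            "batch_size": config.federated.batch_size,
            "learning_rate": config.federated.learning_rate,
            "n_rounds": config.federated.n_rounds,
            "seed": config.federated.seed,
        },
        "mask_spec": {
            "threshold": config.mask_spec.threshold,
            "occlusion_fill": config.mask_spec.occlusion_fill,
            "retain_fill": config.mask_spec.retain_fill,
        },
        "seeds": list(config.seeds),
        "log_level": config.log_level,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
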