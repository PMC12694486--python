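"""In-memory labeled image collection shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CLASS_NAMES, N_CLASSES


@dataclass
class LabeledImages:
    """A batch of 48x48x1 images in [0,1] with 4-class labels.

    ``masks`` optionally carries per-sample ground-truth discriminative-region
    masks (synthetic data only).
    """

    images: np.ndarray
    labels: np.ndarray
    masks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim == 3:
            self.images = self.images[..., None]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.labels.size and not np.all((self.labels >= 0) & (self.labels < N_CLASSES)):
            raise ValueError(f"labels must lie in [0, {N_CLASSES})")
        if self.masks is not None:
            self.masks = np.asarray(self.masks, dtype=bool)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "LabeledImages":
        idx = np.asarray(idx)
        return LabeledImages(
            self.images[idx], self.labels[idx],
            None if self.masks is None else self.masks[idx],
        )

    def class_counts(self) -> dict[str, int]:
        return {name: int((self.labels == i).sum()) for i, name in enumerate(CLASS_NAMES)}


def concatenate(datasets: list[LabeledImages]) -> LabeledImages:
    if not datasets:
        raise ValueError("cannot concatenate an empty list of datasets")
    masks = None
    if all(d.masks is not None for d in datasets):
        masks = np.concatenate([d.masks for d in datasets])
    return LabeledImages(
        np.concatenate([d.images for d in datasets]),
        np.concatenate([d.labels for d in datasets]),
        masks,
    )
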