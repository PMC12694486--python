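"""Perturbation-based faithfulness metrics for saliency explanations.

Seven quantities per class and model:

- IAUC / DAUC: area under the target-class confidence curve as the most
  salient pixels are progressively restored onto a Gaussian-blurred baseline
  (insertion, higher better) or blacked out (deletion, lower better).
- AD (average drop): mean clamped relative confidence loss when the salient
  region (normalized saliency >= threshold) is occluded — higher means the
  highlighted pixels mattered.
- IC (increase in confidence): fraction of samples whose confidence strictly
  rises when only the salient region is retained.
- ADA / accuracy-after-masking: accuracy lost / remaining after occluding the
  salient region. On a subset the models classify correctly the two sum to 1.
- Active pixel ratio: fraction of pixels above the binarization threshold —
  compactness of the explanation.

The evaluation subset is the intersection of samples correctly classified by
every model under comparison, so that metric differences reflect explanation
quality rather than raw accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import CLASS_NAMES, MaskSpec
from .data import LabeledImages
from .explain import SaliencyMap, explain
from .nn.network import NetworkModel

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "original_confidence", "iauc", "dauc", "ad", "ic", "ada",
    "active_pixels", "accuracy_after_masking",
)


@dataclass
class PerturbationCurve:
    fractions: np.ndarray
    confidences: np.ndarray

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.confidences, self.fractions))


@dataclass
class XaiMetricReport:
    """Per-class and macro (unweighted class-mean) values of the metric suite."""

    per_class: dict[str, dict[str, float]]
    n_samples: dict[str, int]
    macro: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.macro = macro_aggregate(self.per_class)


def macro_aggregate(per_class: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted arithmetic mean of the per-class metric rows."""
    keys = next(iter(per_class.values())).keys()
    return {
        k: float(np.mean([row[k] for row in per_class.values()])) for k in keys
    }


# ----------------------------------------------------------------- primitives

def binarize(saliency: SaliencyMap | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: pixel is salient iff normalized value >= threshold."""
    values = saliency.values if isinstance(saliency, SaliencyMap) else saliency
    return np.asarray(values) >= threshold


def active_pixel_ratio(mask: np.ndarray) -> float:
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum() / mask.size)


def occlude_salient(image: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Set salient (mask=1) pixels to ``fill``; the input is not modified."""
    out = np.array(image, copy=True)
    out[np.asarray(mask, dtype=bool)] = fill
    return out


def retain_salient(image: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Set non-salient (mask=0) pixels to ``fill``; the input is not modified."""
    out = np.array(image, copy=True)
    out[~np.asarray(mask, dtype=bool)] = fill
    return out


def _saliency_order(values: np.ndarray) -> np.ndarray:
    """Pixel indices by descending saliency; ties broken row-major."""
    flat = np.asarray(values, dtype=np.float64).ravel()
    return np.argsort(-flat, kind="stable")


def _curve(
    model: NetworkModel,
    start_image: np.ndarray,
    final_pixels: np.ndarray,
    order: np.ndarray,
    target_class: int,
    n_steps: int,
) -> PerturbationCurve:
    """Shared insertion/deletion machinery: at fraction f the top floor(f*H*W)
    ranked pixels take their ``final_pixels`` value; all perturbed images are
    scored in one batch."""
    h, w = start_image.shape[:2]
    total = h * w
    fractions = np.linspace(0.0, 1.0, n_steps + 1)
    batch = np.empty((n_steps + 1, h, w, 1), dtype=np.float32)
    img = np.array(start_image, copy=True).reshape(h, w, 1).astype(np.float32)
    final_flat = np.asarray(final_pixels, dtype=np.float32).ravel()
    prev_k = 0
    for i, f in enumerate(fractions):
        k = int(np.floor(f * total))
        if k > prev_k:
            idx = order[prev_k:k]
            img.reshape(-1)[idx] = final_flat[idx]
            prev_k = k
        batch[i] = img
    conf = model.predict_proba(batch)[:, int(target_class)]
    return PerturbationCurve(fractions=fractions, confidences=conf.astype(np.float64))


def deletion_curve(
    model: NetworkModel,
    image: np.ndarray,
    saliency: SaliencyMap | np.ndarray,
    target_class: int | None = None,
    n_steps: int = 100,
) -> PerturbationCurve:
    """Progressively black out the most salient pixels of the original image."""
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    if values.min() < 0 or values.max() > 1:
        raise ValueError("saliency map must be normalized to [0, 1]")
    if target_class is None:
        target_class = saliency.target_class  # type: ignore[union-attr]
    image2d = np.asarray(image, dtype=np.float32).reshape(values.shape)
    return _curve(model, image2d, np.zeros_like(image2d), _saliency_order(values),
                  target_class, n_steps)


def insertion_curve(
    model: NetworkModel,
    image: np.ndarray,
    saliency: SaliencyMap | np.ndarray,
    target_class: int | None = None,
    n_steps: int = 100,
    blur_sigma: float = 5.0,
) -> PerturbationCurve:
    """Progressively restore the most salient original pixels onto a
    Gaussian-blurred copy (sigma in pixels)."""
    values = saliency.values if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    if values.min() < 0 or values.max() > 1:
        raise ValueError("saliency map must be normalized to [0, 1]")
    if target_class is None:
        target_class = saliency.target_class  # type: ignore[union-attr]
    image2d = np.asarray(image, dtype=np.float32).reshape(values.shape)
    blurred = gaussian_filter(image2d, sigma=blur_sigma)
    return _curve(model, blurred, image2d, _saliency_order(values),
                  target_class, n_steps)


def average_drop(pairs: list[tuple[float, float]]) -> float:
    """AD = mean over samples of max(0, (p - o)/p); p=0 samples are excluded."""
    kept = [(p, o) for p, o in pairs if p > 0]
    if len(kept) < len(pairs):
        logger.warning("average_drop: excluded %d samples with zero original "
                       "confidence", len(pairs) - len(kept))
    if not kept:
        raise ValueError("average_drop: no samples with positive confidence")
    return float(np.mean([max(0.0, (p - o) / p) for p, o in kept]))


def increase_in_confidence(pairs: list[tuple[float, float]]) -> float:
    """IC = fraction of samples where the retained-only confidence strictly
    exceeds the full-image confidence."""
    if not pairs:
        raise ValueError("increase_in_confidence: empty input")
    return float(np.mean([1.0 if o > p else 0.0 for p, o in pairs]))


def ada_and_masked_accuracy(
    labels: np.ndarray, preds_original: np.ndarray, preds_occluded: np.ndarray
) -> tuple[float, float]:
    """(ADA, accuracy after masking) = (acc(original) - acc(occluded), acc(occluded))."""
    labels = np.asarray(labels)
    acc_orig = float(np.mean(np.asarray(preds_original) == labels))
    acc_mask = float(np.mean(np.asarray(preds_occluded) == labels))
    return acc_orig - acc_mask, acc_mask


# ------------------------------------------------------------------ the suite

def evaluate_suite(
    models: list[NetworkModel],
    dataset: LabeledImages,
    layer: str | None = None,
    mask_spec: MaskSpec = MaskSpec(),
    n_steps: int = 100,
    saliency_fn=None,
) -> list[XaiMetricReport]:
    """Run the full seven-metric suite for each model.

    The evaluation subset is restricted to samples correctly classified by
    every model in ``models``. ``saliency_fn(model, image, label) ->
    SaliencyMap`` may override the default Grad-CAM++ + attention pipeline
    (used e.g. for informed/random baselines).
    """
    if not models:
        raise ValueError("need at least one model")
    correct = np.ones(len(dataset), dtype=bool)
    for model in models:
        correct &= model.predict(dataset.images) == dataset.labels
    if not correct.any():
        raise ValueError(
            "no sample is correctly classified by all models; "
            "evaluate on more data or better-trained models"
        )
    subset = dataset.subset(np.flatnonzero(correct))

    reports = []
    for model in models:
        reports.append(_suite_one_model(
            model, subset, layer, mask_spec, n_steps, saliency_fn))
    return reports


def _suite_one_model(
    model: NetworkModel,
    subset: LabeledImages,
    layer: str | None,
    mask_spec: MaskSpec,
    n_steps: int,
    saliency_fn,
) -> XaiMetricReport:
    per_class: dict[str, dict[str, float]] = {}
    n_samples: dict[str, int] = {}
    probs_full = model.predict_proba(subset.images)
    preds_full = probs_full.argmax(axis=1)

    for label, name in enumerate(CLASS_NAMES):
        idx = np.flatnonzero(subset.labels == label)
        if idx.size == 0:
            continue
        iaucs, daucs, actives = [], [], []
        ad_pairs, ic_pairs = [], []
        preds_occluded = []
        for i in idx:
            image = subset.images[i, ..., 0]
            p = float(probs_full[i, label])
            if saliency_fn is None:
                smap = explain(model, subset.images[i], label, layer)
            else:
                smap = saliency_fn(model, subset.images[i], label)
            iaucs.append(insertion_curve(model, image, smap, label, n_steps).auc)
            daucs.append(deletion_curve(model, image, smap, label, n_steps).auc)
            mask = binarize(smap, mask_spec.threshold)
            actives.append(active_pixel_ratio(mask))
            occ = occlude_salient(image, mask, mask_spec.occlusion_fill)
            ret = retain_salient(image, mask, mask_spec.retain_fill)
            probs_pair = model.predict_proba(np.stack([occ, ret])[..., None])
            ad_pairs.append((p, float(probs_pair[0, label])))
            ic_pairs.append((p, float(probs_pair[1, label])))
            preds_occluded.append(int(probs_pair[0].argmax()))
        ada, acc_mask = ada_and_masked_accuracy(
            subset.labels[idx], preds_full[idx], np.array(preds_occluded))
        per_class[name] = {
            "original_confidence": float(probs_full[idx, label].mean()),
            "iauc": float(np.mean(iaucs)),
            "dauc": float(np.mean(daucs)),
            "ad": average_drop(ad_pairs),
            "ic": increase_in_confidence(ic_pairs),
            "ada": ada,
            "active_pixels": float(np.mean(actives)),
            "accuracy_after_masking": acc_mask,
        }
        n_samples[name] = int(idx.size)
    return XaiMetricReport(per_class=per_class, n_samples=n_samples)
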