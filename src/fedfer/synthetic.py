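"""Seeded generator of schematic 48x48 grayscale "faces" with known
discriminative regions.

Every sample shares a face-oval outline and two eyes; class identity is
carried only by the mouth curvature (upward arc = happy, downward arc = sad,
flat = neutral/angry) and the eyebrow slant (inward-down = angry, flat
otherwise). Angry and neutral therefore differ only in the brows, which keeps
the task non-trivial. The ground-truth mask is the dilated union of the mouth
and brow strokes — exactly the pixels a faithful explanation should highlight.

The face interior is deliberately black: the discriminative strokes are bright
marks on a zero background, so occluding them with the metric suite's black
fill genuinely erases the class signal rather than leaving a silhouette of the
same shape (which a filled face would).

Per-sample variation: independent integer jitter of each face part, a small
whole-image rotation, a multiplicative contrast factor and additive Gaussian
noise, all drawn from one seeded Generator.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.draw import disk, ellipse_perimeter, line

from .config import CLASS_NAMES, SyntheticSpec
from .data import LabeledImages

_FACE_INTENSITY = 0.55
_FEATURE_INTENSITY = 0.95
_SIZE = 48


def _draw_stroke(canvas: np.ndarray, stroke: np.ndarray,
                 points: list[tuple[int, int]]) -> None:
    """Polyline through ``points``; paints both the canvas and the stroke mask."""
    for (r0, c0), (r1, c1) in zip(points[:-1], points[1:]):
        rr, cc = line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < _SIZE) & (cc >= 0) & (cc < _SIZE)
        canvas[rr[ok], cc[ok]] = _FEATURE_INTENSITY
        stroke[rr[ok], cc[ok]] = True


def _mouth_points(label: int, jitter: tuple[int, int]) -> list[tuple[int, int]]:
    base_r, base_c = 34 + jitter[0], 24 + jitter[1]
    pts = []
    for dx in range(-7, 8):
        # happy: corners curl up (smaller row); sad: corners curl down; flat else
        offset = round(4.0 * (dx / 7.0) ** 2)
        if CLASS_NAMES[label] == "happy":
            r = base_r - offset
        elif CLASS_NAMES[label] == "sad":
            r = base_r + offset - 2
        else:  # neutral, angry: flat mouth
            r = base_r
        pts.append((r, base_c + dx))
    return pts


def _brow_points(label: int, jitter: tuple[int, int]) -> list[list[tuple[int, int]]]:
    jr, jc = jitter
    if CLASS_NAMES[label] == "angry":
        # inner ends pulled down toward the nose
        left = [(11 + jr, 11 + jc), (15 + jr, 19 + jc)]
        right = [(15 + jr, 28 + jc), (11 + jr, 36 + jc)]
    else:
        left = [(12 + jr, 11 + jc), (12 + jr, 19 + jc)]
        right = [(12 + jr, 28 + jc), (12 + jr, 36 + jc)]
    return [left, right]


def _render(label: int, rng: np.random.Generator,
            spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    canvas = np.zeros((_SIZE, _SIZE), dtype=np.float64)
    stroke = np.zeros((_SIZE, _SIZE), dtype=bool)
    j = spec.jitter_px

    def jit() -> tuple[int, int]:
        return (int(rng.integers(-j, j + 1)), int(rng.integers(-j, j + 1))) if j else (0, 0)

    # common parts: face-oval outline (black interior) + eyes
    face_j = jit()
    rr, cc = ellipse_perimeter(24 + face_j[0], 24 + face_j[1], 21, 17,
                               shape=canvas.shape)
    outline = np.zeros_like(canvas, dtype=bool)
    outline[rr, cc] = True
    canvas[ndimage.binary_dilation(outline, iterations=1)] = _FACE_INTENSITY
    eye_j = jit()
    for ec in (16, 31):
        rr, cc = disk((19 + eye_j[0], ec + eye_j[1]), 2.2, shape=canvas.shape)
        canvas[rr, cc] = _FEATURE_INTENSITY

    # discriminative parts
    for seg in _brow_points(label, jit()):
        _draw_stroke(canvas, stroke, seg)
    _draw_stroke(canvas, stroke, _mouth_points(label, jit()))

    mask = ndimage.binary_dilation(stroke, iterations=1)

    if spec.rotation_deg > 0:
        angle = float(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
        canvas = ndimage.rotate(canvas, angle, reshape=False, order=1, mode="constant")
        mask = ndimage.rotate(mask.astype(np.float64), angle, reshape=False,
                              order=0, mode="constant") > 0.5

    lo, hi = spec.contrast_range
    canvas *= rng.uniform(lo, hi)
    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, size=canvas.shape)
    return np.clip(canvas, 0.0, 1.0).astype(np.float32), mask


def generate_dataset(spec: SyntheticSpec) -> LabeledImages:
    """Class-balanced schematic-face dataset, deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    images, labels, masks = [], [], []
    for label in range(len(CLASS_NAMES)):
        for _ in range(spec.n_per_class):
            img, mask = _render(label, rng, spec)
            images.append(img)
            labels.append(label)
            masks.append(mask)
    return LabeledImages(np.stack(images), np.array(labels), np.stack(masks))


def train_test_split_synthetic(
    samples: LabeledImages, test_fraction: float = 0.2, seed: int = 0
) -> tuple[LabeledImages, LabeledImages]:
    """Stratified, seeded, disjoint split."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in np.unique(samples.labels):
        idx = np.flatnonzero(samples.labels == label)
        idx = rng.permutation(idx)
        n_test = int(round(len(idx) * test_fraction))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return samples.subset(np.sort(train_idx)), samples.subset(np.sort(test_idx))
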