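"""Grad-CAM++ saliency from any filter block, plus the final overlay that
modulates it with a parameter-free channel-attention map.

The class score Y_c is the pre-softmax logit. First-order gradients
dY_c/dA^k are exact (reverse-mode through the layers above the block).
Following the standard closed-form treatment for networks where the feature
map feeds linear+ReLU paths, the second- and third-order partials entering the
alpha coefficients are taken as the elementwise square and cube of the
first-order gradient.

The channel-attention map is computed post hoc without trained parameters:
per-channel scores are the sum of global-average- and global-max-pooled
activations, passed through a softmax over channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn.network import NetworkModel

_EPS = 1e-8


@dataclass
class SaliencyMap:
    """Per-pixel relevance in [0,1] at input resolution."""

    values: np.ndarray
    target_class: int
    source_layer: str


@dataclass
class GradientBundle:
    """Feature maps A^k of one block and the partials of Y_c w.r.t. them."""

    activations: np.ndarray  # (H, W, K)
    grad1: np.ndarray
    grad2: np.ndarray
    grad3: np.ndarray
    target_class: int
    source_layer: str


@dataclass
class AttentionProfile:
    """Non-negative per-channel weights summing to 1."""

    channel_weights: np.ndarray
    source_layer: str


def gradient_bundle(
    model: NetworkModel, image: np.ndarray, target_class: int, layer: str
) -> GradientBundle:
    """Activations and first/second/third-order partials of the class logit."""
    acts, g1 = model.grad_logit_wrt_block(image, target_class, layer)
    return GradientBundle(
        activations=acts,
        grad1=g1,
        grad2=g1 ** 2,
        grad3=g1 ** 3,
        target_class=int(target_class),
        source_layer=layer,
    )


def gradcampp_map(bundle: GradientBundle) -> np.ndarray:
    """Raw (layer-resolution, non-normalized) Grad-CAM++ map.

    alpha_ij^k = grad2 / (2*grad2 + sum_ab(A^k) * grad3), zero where the
    denominator vanishes; w_k = sum_ij alpha * relu(grad1);
    map = relu(sum_k w_k A^k).
    """
    A, g1, g2, g3 = bundle.activations, bundle.grad1, bundle.grad2, bundle.grad3
    channel_sum = A.sum(axis=(0, 1), keepdims=True)  # (1, 1, K)
    denom = 2.0 * g2 + channel_sum * g3
    alpha = np.divide(g2, denom, out=np.zeros_like(g2), where=denom != 0)
    weights = (alpha * np.maximum(g1, 0.0)).sum(axis=(0, 1))  # (K,)
    return np.maximum((weights * A).sum(axis=2), 0.0)


def normalize_and_upsample(
    raw: np.ndarray, target_class: int = -1, source_layer: str = ""
) -> SaliencyMap:
    """Min-max normalize to [0,1] (constant maps collapse to all zeros) and
    bilinearly upsample to 48x48. The normalization is re-applied after
    interpolation so a non-constant map always attains max 1."""
    vals = _minmax(np.asarray(raw, dtype=np.float64))
    if vals.shape != (48, 48):
        vals = resize(vals, (48, 48), order=1, mode="edge", anti_aliasing=False)
        vals = _minmax(vals)
    return SaliencyMap(values=vals, target_class=target_class, source_layer=source_layer)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < _EPS:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def channel_attention(
    model: NetworkModel, image: np.ndarray, layer: str
) -> AttentionProfile:
    """Parameter-free channel attention: softmax over (GAP + GMP) channel scores."""
    acts = model.block_activations(np.asarray(image)[None] if np.asarray(image).ndim < 4
                                   else np.asarray(image))
    if layer not in acts:
        raise KeyError(f"unknown layer {layer!r}; known: {list(acts)}")
    A = acts[layer][0]  # (H, W, K)
    scores = A.mean(axis=(0, 1)) + A.max(axis=(0, 1))
    z = scores - scores.max()
    w = np.exp(z)
    w /= w.sum()
    return AttentionProfile(channel_weights=w.astype(np.float64), source_layer=layer)


def combined_overlay(
    gcpp: SaliencyMap, attn: AttentionProfile, bundle: GradientBundle
) -> SaliencyMap:
    """Final overlay: Grad-CAM++ map multiplied by the attention spatial map
    (normalized channel-weighted sum of relu(A^k)), re-normalized to [0,1]."""
    if not (gcpp.source_layer == attn.source_layer == bundle.source_layer):
        raise ValueError(
            f"source layers differ: {gcpp.source_layer!r}, {attn.source_layer!r}, "
            f"{bundle.source_layer!r}"
        )
    A = np.maximum(bundle.activations, 0.0)
    raw_attn = (attn.channel_weights * A).sum(axis=2)
    if float(raw_attn.max()) - float(raw_attn.min()) < _EPS:
        # a spatially constant attention map carries no information: leave the
        # Grad-CAM++ map unmodulated rather than suppressing everything
        attn_values = np.ones_like(gcpp.values)
    else:
        attn_values = normalize_and_upsample(
            raw_attn, gcpp.target_class, gcpp.source_layer
        ).values
    product = gcpp.values * attn_values
    return SaliencyMap(
        values=_minmax(product),
        target_class=gcpp.target_class,
        source_layer=gcpp.source_layer,
    )


def explain(
    model: NetworkModel, image: np.ndarray, target_class: int, layer: str | None = None
) -> SaliencyMap:
    """Full pipeline: Grad-CAM++ at ``layer`` (default: last filter block)
    combined with channel attention, at input resolution in [0,1]."""
    if layer is None:
        layer = model.config.block_names[-1]
    bundle = gradient_bundle(model, image, target_class, layer)
    gcpp = normalize_and_upsample(gradcampp_map(bundle), target_class, layer)
    attn = channel_attention(model, image, layer)
    return combined_overlay(gcpp, attn, bundle)
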