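"""Figure export: color-mapped saliency overlays and the two-panel radar
comparison of higher-is-better vs lower-is-better explanation metrics."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import HIGHER_BETTER, LOWER_BETTER  # noqa: E402


def save_overlay_png(image: np.ndarray, saliency: np.ndarray, path,
                     alpha: float = 0.5) -> None:
    """Heatmap (jet) blended over the grayscale image."""
    fig, ax = plt.subplots(figsize=(2, 2), dpi=96)
    ax.imshow(np.asarray(image).squeeze(), cmap="gray", vmin=0, vmax=1)
    ax.imshow(np.asarray(saliency), cmap="jet", vmin=0, vmax=1, alpha=alpha)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def _radar(ax, metric_names: list[str], rows: dict[str, list[float]], title: str) -> None:
    angles = np.linspace(0, 2 * np.pi, len(metric_names), endpoint=False).tolist()
    angles += angles[:1]
    for model_name, values in rows.items():
        vals = list(values) + [values[0]]
        ax.plot(angles, vals, label=model_name)
        ax.fill(angles, vals, alpha=0.15)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(metric_names, fontsize=7)
    ax.set_ylim(0, 1)
    ax.set_title(title, fontsize=9)


def save_radar_png(macros: dict[str, dict[str, float]], path) -> None:
    """Two radar panels: left higher-is-better, right lower-is-better metrics.

    ``macros`` maps model name -> macro metric row.
    """
    fig, axes = plt.subplots(
        1, 2, figsize=(9, 4.5), subplot_kw={"projection": "polar"})
    _radar(axes[0], list(HIGHER_BETTER),
           {m: [row[k] for k in HIGHER_BETTER] for m, row in macros.items()},
           "Higher is better")
    _radar(axes[1], list(LOWER_BETTER),
           {m: [row[k] for k in LOWER_BETTER] for m, row in macros.items()},
           "Lower is better")
    axes[1].legend(loc="upper right", bbox_to_anchor=(1.4, 1.1), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
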