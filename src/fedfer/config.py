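"""Configuration objects for the architecture family, federated protocol and metrics.

The four-emotion label space (neutral, happy, sad, angry) is fixed across the
whole package; class indices follow the listing order of the architecture's
output layer: neutral=0, happy=1, sad=2, angry=3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

CLASS_NAMES: tuple[str, ...] = ("neutral", "happy", "sad", "angry")
N_CLASSES = 4

#: seeds used for multi-seed statistical evaluation
DEFAULT_SEEDS: tuple[int, ...] = (1, 3, 7, 17, 21, 33, 42, 55, 77, 100)


class InfeasibleArchitectureError(ValueError):
    """Raised when a filter-block configuration collapses the spatial extent to zero."""


def spatial_trace(
    n_blocks: int, input_height: int = 48, input_width: int = 48
) -> list[tuple[int, int]]:
    """Spatial (height, width) after each conv(3x3, valid) and pool(2x2, floor) stage.

    Returns the interleaved trace ``[post-conv1, post-pool1, post-conv2, ...]``.
    Raises :class:`InfeasibleArchitectureError` if any stage reaches zero extent,
    naming the offending block.
    """
    h, w = input_height, input_width
    trace: list[tuple[int, int]] = []
    for b in range(1, n_blocks + 1):
        h, w = h - 2, w - 2  # 3x3 valid convolution
        if h < 1 or w < 1:
            raise InfeasibleArchitectureError(
                f"infeasible architecture: conv of block FB{b} reduces spatial size to "
                f"{h}x{w}"
            )
        trace.append((h, w))
        h, w = h // 2, w // 2  # 2x2 max-pool, stride 2, floor
        if h < 1 or w < 1:
            raise InfeasibleArchitectureError(
                f"infeasible architecture: pool of block FB{b} reduces spatial size to "
                f"{h}x{w}"
            )
        trace.append((h, w))
    return trace


@dataclass(frozen=True)
class ArchitectureConfig:
    """One candidate of the lightweight CNN family.

    ``filter_blocks`` gives the channel width of each conv(3x3)+maxpool(2x2)
    stage (FB1..FB4). The classifier head is fixed: dense 256 -> dense 128 ->
    dropout -> softmax over the four emotions.
    """

    filter_blocks: tuple[int, ...]
    input_height: int = 48
    input_width: int = 48
    input_channels: int = 1
    dense_units: tuple[int, int] = (256, 128)
    dropout_rate: float = 0.2
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        fb = tuple(int(f) for f in self.filter_blocks)
        object.__setattr__(self, "filter_blocks", fb)
        if len(fb) not in (3, 4):
            raise ValueError(
                f"filter_blocks must have length 3 or 4, got {len(fb)}"
            )
        if any(f < 1 for f in fb):
            raise ValueError(f"filter block widths must be >= 1, got {fb}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        # raises InfeasibleArchitectureError when the trace collapses
        spatial_trace(len(fb), self.input_height, self.input_width)

    @property
    def n_blocks(self) -> int:
        return len(self.filter_blocks)

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(f"FB{i + 1}" for i in range(self.n_blocks))

    def trace(self) -> list[tuple[int, int]]:
        return spatial_trace(self.n_blocks, self.input_height, self.input_width)

    @property
    def flatten_length(self) -> int:
        h, w = self.trace()[-1]
        return h * w * self.filter_blocks[-1]


@dataclass(frozen=True)
class FederatedConfig:
    """Protocol parameters of the FedAvg simulation."""

    n_clients: int = 3
    local_epochs: int = 15
    batch_size: int = 64
    learning_rate: float = 0.001
    n_rounds: int = 20
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_clients", "local_epochs", "batch_size", "n_rounds"):
            if getattr(self, name) < (0 if name == "local_epochs" else 1):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class MaskSpec:
    """Binarization threshold and fill values used by the perturbation metrics."""

    threshold: float = 0.5
    occlusion_fill: float = 0.0
    retain_fill: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the schematic-face generator."""

    n_per_class: int = 500
    seed: int = 42
    jitter_px: int = 2
    rotation_deg: float = 5.0
    noise_sigma: float = 0.05
    contrast_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.jitter_px < 0 or self.rotation_deg < 0 or self.noise_sigma < 0:
            raise ValueError("jitter_px, rotation_deg and noise_sigma must be >= 0")
        if self.noise_sigma >= 0.5:
            raise ValueError("noise_sigma must be < 0.5")
        lo, hi = self.contrast_range
        if not (0 < lo <= hi):
            raise ValueError("contrast_range must satisfy 0 < lo <= hi")


@dataclass
class RunConfig:
    """Top-level configuration mirroring the experimental protocol."""

    architecture: ArchitectureConfig = field(
        default_factory=lambda: ArchitectureConfig((64, 128, 256))
    )
    federated: FederatedConfig = field(default_factory=FederatedConfig)
    mask_spec: MaskSpec = field(default_factory=MaskSpec)
    seeds: Sequence[int] = DEFAULT_SEEDS
    log_level: str = "INFO"
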