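"""Exact parameter, multiply-accumulate and size accounting for the CNN family.

Conventions: a conv layer costs ``3*3*c_in*c_out + c_out`` parameters and
``out_h*out_w*c_out*(9*c_in)`` MACs; a dense layer ``in*out + out`` parameters
and ``in*out`` MACs. FLOPs count 2 per MAC in conv/dense layers only; bias
additions, pooling, activations and softmax are excluded. Serialized size
assumes float32 storage, reported in binary megabytes.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..config import ArchitectureConfig


@dataclass(frozen=True)
class LayerSummary:
    layer_name: str
    output_shape: tuple[int, ...]
    parameter_count: int
    mac_count: int


def layer_summaries(config: ArchitectureConfig) -> list[LayerSummary]:
    """Per-layer table whose parameter/MAC columns sum to the model totals."""
    rows: list[LayerSummary] = []
    h, w = config.input_height, config.input_width
    c_in = config.input_channels
    for i, c_out in enumerate(config.filter_blocks):
        oh, ow = h - 2, w - 2
        rows.append(LayerSummary(
            layer_name=f"FB{i + 1}_conv",
            output_shape=(oh, ow, c_out),
            parameter_count=9 * c_in * c_out + c_out,
            mac_count=oh * ow * c_out * 9 * c_in,
        ))
        h, w = oh // 2, ow // 2
        rows.append(LayerSummary(f"FB{i + 1}_pool", (h, w, c_out), 0, 0))
        c_in = c_out

    n_in = h * w * c_in
    rows.append(LayerSummary("flatten", (n_in,), 0, 0))
    for j, units in enumerate(config.dense_units):
        rows.append(LayerSummary(
            f"dense{j + 1}", (units,), n_in * units + units, n_in * units))
        n_in = units
    rows.append(LayerSummary("dropout", (n_in,), 0, 0))
    rows.append(LayerSummary(
        "output", (config.n_classes,),
        n_in * config.n_classes + config.n_classes, n_in * config.n_classes))
    return rows


def count_parameters(config: ArchitectureConfig) -> int:
    """Exact trainable parameter count, biases included."""
    return sum(r.parameter_count for r in layer_summaries(config))


def count_flops(config: ArchitectureConfig) -> int:
    """FLOPs per inference: 2 per MAC, conv and dense layers only."""
    return 2 * sum(r.mac_count for r in layer_summaries(config))


def serialized_size(config: ArchitectureConfig) -> float:
    """Float32 weight storage in binary megabytes, rounded to 2 decimals."""
    return round(count_parameters(config) * 4 / 2 ** 20, 2)
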