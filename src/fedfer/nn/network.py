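"""The configurable lightweight CNN: construction, inference, and the hooks the
Grad-CAM++ explainer needs (named access to each filter block's post-activation
feature maps and gradients of a class logit with respect to them).
"""

from __future__ import annotations

import io
import json

import numpy as np

from ..config import ArchitectureConfig
from .layers import Conv2D, Dense, Dropout, Flatten, Layer, MaxPool2D, ReLU, softmax

#: WeightSet: ordered mapping name -> array, the unit of FedAvg aggregation
WeightSet = dict[str, np.ndarray]


class NetworkModel:
    """A stack of conv(3x3)+ReLU+maxpool(2x2) filter blocks followed by a
    dense 256/128 head with dropout and a 4-way softmax output.

    Weight initialization is He-uniform for conv/dense kernels with zero
    biases, fully determined by the construction seed.
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        self.layers: list[Layer] = []
        #: index into ``self.layers`` of each block's post-activation ReLU
        self.block_relu_index: dict[str, int] = {}

        c_in = config.input_channels
        for i, c_out in enumerate(config.filter_blocks):
            name = f"FB{i + 1}"
            self.layers.append(Conv2D(c_in, c_out, name=f"{name}_conv"))
            self.layers.append(ReLU(name=f"{name}_relu"))
            self.block_relu_index[name] = len(self.layers) - 1
            self.layers.append(MaxPool2D(name=f"{name}_pool"))
            c_in = c_out

        self.layers.append(Flatten(name="flatten"))
        n_in = config.flatten_length
        for j, units in enumerate(config.dense_units):
            self.layers.append(Dense(n_in, units, name=f"dense{j + 1}"))
            self.layers.append(ReLU(name=f"dense{j + 1}_relu"))
            n_in = units
        self.layers.append(Dropout(config.dropout_rate, name="dropout"))
        self.layers.append(Dense(n_in, config.n_classes, name="output"))

        self._init_weights(seed)

    # ------------------------------------------------------------------ setup
    def _init_weights(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            if isinstance(layer, Conv2D):
                fan_in = 9 * layer.c_in
            elif isinstance(layer, Dense):
                fan_in = layer.n_in
            else:
                continue
            limit = np.sqrt(6.0 / fan_in)
            layer.W[...] = rng.uniform(-limit, limit, size=layer.W.shape).astype(
                np.float32
            )
            layer.b[...] = 0.0

    # -------------------------------------------------------------- inference
    def _check_images(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        cfg = self.config
        want = (cfg.input_height, cfg.input_width, cfg.input_channels)
        if x.ndim != 4 or x.shape[1:] != want:
            raise ValueError(
                f"expected images of shape (N, {want[0]}, {want[1]}, {want[2]}), "
                f"got {np.asarray(images).shape}"
            )
        return x

    def forward(self, images: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the network and return pre-softmax logits ``(N, n_classes)``."""
        x = self._check_images(images)
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-class probabilities; dropout inactive; rows sum to 1."""
        return softmax(self.forward(images, training=False))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images, training=False).argmax(axis=1)

    def block_activations(self, images: np.ndarray) -> dict[str, np.ndarray]:
        """Post-ReLU (pre-pool) feature maps A^k of every filter block."""
        x = self._check_images(images)
        index_to_name = {v: k for k, v in self.block_relu_index.items()}
        acts: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, training=False)
            if i in index_to_name:
                acts[index_to_name[i]] = x
        return acts

    def forward_from_block(self, block: str, activations: np.ndarray) -> np.ndarray:
        """Compute logits from injected post-activation feature maps of ``block``.

        Used by the finite-difference oracle for explanation gradients.
        """
        if block not in self.block_relu_index:
            raise KeyError(f"unknown layer {block!r}; known: {list(self.block_relu_index)}")
        x = np.asarray(activations, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        for layer in self.layers[self.block_relu_index[block] + 1:]:
            x = layer.forward(x, training=False)
        return x

    def grad_logit_wrt_block(
        self, image: np.ndarray, target_class: int, block: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, dY_c/dA) for one image, where A is the post-activation
        feature map of ``block`` and Y_c the pre-softmax logit of
        ``target_class``."""
        if block not in self.block_relu_index:
            raise KeyError(f"unknown layer {block!r}; known: {list(self.block_relu_index)}")
        x = self._check_images(np.asarray(image)[None] if np.asarray(image).ndim < 4
                               else np.asarray(image))
        idx = self.block_relu_index[block]
        acts = x
        cached: np.ndarray | None = None
        for i, layer in enumerate(self.layers):
            acts = layer.forward(acts, training=False)
            if i == idx:
                cached = acts
        logits = acts
        dout = np.zeros_like(logits)
        dout[:, int(target_class)] = 1.0
        for layer in reversed(self.layers[idx + 1:]):
            dout = layer.backward(dout)
        return cached[0], dout[0]

    # ---------------------------------------------------------------- weights
    def get_weights(self) -> WeightSet:
        """Ordered copy of every trainable array (value semantics)."""
        ws: WeightSet = {}
        for layer in self.layers:
            for name, arr in layer.params().items():
                ws[name] = arr.copy()
        return ws

    def set_weights(self, weights: WeightSet) -> None:
        own = {}
        for layer in self.layers:
            own.update(layer.params())
        if list(own) != list(weights):
            raise ValueError("weight-set names/order do not match this architecture")
        for name, arr in weights.items():
            if own[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{own[name].shape} vs {arr.shape}")
            own[name][...] = arr

    # ------------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        """Single-archive checkpoint: config echo + ordered named weights."""
        meta = json.dumps({
            "filter_blocks": list(self.config.filter_blocks),
            "dense_units": list(self.config.dense_units),
            "dropout_rate": self.config.dropout_rate,
            "input_height": self.config.input_height,
            "input_width": self.config.input_width,
            "input_channels": self.config.input_channels,
            "n_classes": self.config.n_classes,
            "weight_order": list(self.get_weights()),
        })
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.get_weights())

    @classmethod
    def load(cls, path) -> "NetworkModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            cfg = ArchitectureConfig(
                filter_blocks=tuple(meta["filter_blocks"]),
                dense_units=tuple(meta["dense_units"]),
                dropout_rate=meta["dropout_rate"],
                input_height=meta["input_height"],
                input_width=meta["input_width"],
                input_channels=meta["input_channels"],
                n_classes=meta["n_classes"],
            )
            model = cls(cfg, seed=0)
            model.set_weights({name: data[name] for name in meta["weight_order"]})
        return model


def build_network(config: ArchitectureConfig, seed: int) -> NetworkModel:
    """Construct the CNN for ``config`` with seeded deterministic initialization."""
    return NetworkModel(config, seed=seed)
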