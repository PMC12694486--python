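"""Adam optimizer and the shared mini-batch training loop.

Both centralized and per-client federated training go through
:func:`sgd_train`, which is fully determined by its seed: the permutation of
samples each epoch and the dropout masks are drawn from one Generator. This is
what makes single-client FedAvg bitwise-equivalent to centralized training.
"""

from __future__ import annotations

import numpy as np

from .layers import softmax
from .network import NetworkModel


class Adam:
    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for name, p in params.items():
            g = grads[name]
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


def sgd_train(
    model: NetworkModel,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int,
) -> list[float]:
    """Train ``model`` in place with Adam on softmax cross-entropy.

    Returns the per-epoch mean training loss. A dataset smaller than one batch
    is trained as a single smaller batch.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(lr=lr)
    n = len(labels)
    losses: list[float] = []
    params: dict[str, np.ndarray] = {}
    for layer in model.layers:
        params.update(layer.params())
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = images[idx], labels[idx]
            logits = model.forward(xb, training=True, rng=rng)
            probs = softmax(logits)
            epoch_loss += cross_entropy(probs, yb) * len(idx)
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), yb] -= 1.0
            dlogits /= np.float32(len(idx))
            dout = dlogits.astype(np.float32)
            for layer in reversed(model.layers):
                dout = layer.backward(dout)
            grads: dict[str, np.ndarray] = {}
            for layer in model.layers:
                grads.update(layer.grads())
            opt.step(params, grads)
        losses.append(epoch_loss / n)
    return losses
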