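"""FedAvg simulation over equal, stratified in-process clients, plus the
centralized baseline trained under the identical optimizer and protocol.

Each round: broadcast the global weights, run ``local_epochs`` of Adam on every
client's shard (optimizer state reset each round), then aggregate the client
weight sets with a sample-count-weighted element-wise mean. Shards stay fixed
across rounds; only the local batch order is reseeded per round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ArchitectureConfig, FederatedConfig, N_CLASSES, CLASS_NAMES
from .data import LabeledImages, concatenate
from .nn.network import NetworkModel, WeightSet, build_network
from .nn.optim import sgd_train


@dataclass
class ClientShard:
    client_id: int
    data: LabeledImages

    @property
    def n_samples(self) -> int:
        return len(self.data)


@dataclass
class RoundRecord:
    round_index: int
    client_losses: list[list[float]] = field(default_factory=list)
    global_accuracy: float = float("nan")
    global_f1: float = float("nan")

    @property
    def mean_client_loss(self) -> float:
        finals = [trace[-1] for trace in self.client_losses if trace]
        return float(np.mean(finals)) if finals else float("nan")


def round_seed(seed: int, round_index: int, client_id: int = 0) -> int:
    """Deterministic per-round, per-client seed below 2**31."""
    return int((seed * 1_000_003 + round_index * 10_007 + client_id) % (2 ** 31))


def merge_and_shuffle(datasets: list[LabeledImages], seed: int) -> LabeledImages:
    """Union of the input collections in a seeded random order."""
    merged = concatenate(datasets)
    order = np.random.default_rng(seed).permutation(len(merged))
    return merged.subset(order)


def partition_clients(
    data: LabeledImages, n_clients: int, seed: int
) -> list[ClientShard]:
    """Stratified round-robin split into equal shards.

    After a seeded shuffle, the samples of each class are dealt round-robin to
    the clients, so per-class shard sizes differ by at most one and every class
    is present in every shard; earlier clients receive the remainders.
    """
    if n_clients < 1:
        raise ValueError("n_clients must be >= 1")
    rng = np.random.default_rng(seed)
    assignments: list[list[int]] = [[] for _ in range(n_clients)]
    for label in range(N_CLASSES):
        idx = np.flatnonzero(data.labels == label)
        if len(idx) < n_clients:
            raise ValueError(
                f"too few samples of class {CLASS_NAMES[label]!r}: "
                f"{len(idx)} < {n_clients} clients"
            )
        idx = rng.permutation(idx)
        for i, sample in enumerate(idx):
            assignments[i % n_clients].append(int(sample))
    return [
        ClientShard(client_id=i, data=data.subset(np.array(sorted(rows))))
        for i, rows in enumerate(assignments)
    ]


def local_train(
    start: WeightSet,
    shard: ClientShard,
    cfg: FederatedConfig,
    arch: ArchitectureConfig,
    round_seed_: int,
) -> tuple[WeightSet, list[float]]:
    """One client's local update; ``start`` is left unmodified."""
    model = build_network(arch, seed=0)
    model.set_weights(start)  # set_weights copies -> value semantics
    losses = sgd_train(
        model, shard.data.images, shard.data.labels,
        epochs=cfg.local_epochs, batch_size=cfg.batch_size,
        lr=cfg.learning_rate, seed=round_seed_,
    )
    return model.get_weights(), losses


def fedavg_aggregate(updates: list[WeightSet], counts: list[int]) -> WeightSet:
    """Element-wise weighted mean with weights n_i / sum(n_i)."""
    if not updates:
        raise ValueError("need at least one client update")
    if len(updates) != len(counts):
        raise ValueError("updates and counts length mismatch")
    if any(c <= 0 for c in counts):
        raise ValueError("sample counts must be positive")
    names = list(updates[0])
    for u in updates[1:]:
        if list(u) != names or any(u[k].shape != updates[0][k].shape for k in names):
            raise ValueError("weight sets are not aggregatable: names/shapes differ")
    total = float(sum(counts))
    out: WeightSet = {}
    for name in names:
        acc = np.zeros_like(updates[0][name], dtype=np.float64)
        for u, c in zip(updates, counts):
            acc += (c / total) * u[name].astype(np.float64)
        out[name] = acc.astype(updates[0][name].dtype)
    return out


def _global_metrics(model: NetworkModel, testset: LabeledImages | None) -> tuple[float, float]:
    if testset is None or len(testset) == 0:
        return float("nan"), float("nan")
    from .evaluation import evaluate_classification

    report = evaluate_classification(model, testset)
    return report.accuracy, report.f1


def run_federated(
    data: LabeledImages,
    arch: ArchitectureConfig,
    cfg: FederatedConfig,
    testset: LabeledImages | None = None,
    plateau_rule: bool = False,
    plateau_patience: int = 3,
    plateau_min_gain: float = 0.001,
) -> tuple[NetworkModel, list[RoundRecord]]:
    """FedAvg over ``cfg.n_rounds`` rounds of broadcast / local train / aggregate.

    The optional plateau rule (off by default) stops early when the global
    accuracy has not improved by more than ``plateau_min_gain`` over
    ``plateau_patience`` consecutive rounds.
    """
    shards = partition_clients(data, cfg.n_clients, seed=cfg.seed)
    model = build_network(arch, seed=cfg.seed)
    global_weights = model.get_weights()
    history: list[RoundRecord] = []
    best_acc = -np.inf
    stall = 0
    for r in range(cfg.n_rounds):
        record = RoundRecord(round_index=r)
        updates, counts = [], []
        for shard in shards:
            w, losses = local_train(
                global_weights, shard, cfg, arch,
                round_seed_=round_seed(cfg.seed, r, shard.client_id),
            )
            updates.append(w)
            counts.append(shard.n_samples)
            record.client_losses.append(losses)
        global_weights = fedavg_aggregate(updates, counts)
        model.set_weights(global_weights)
        record.global_accuracy, record.global_f1 = _global_metrics(model, testset)
        history.append(record)
        if plateau_rule and np.isfinite(record.global_accuracy):
            if record.global_accuracy > best_acc + plateau_min_gain:
                best_acc = record.global_accuracy
                stall = 0
            else:
                stall += 1
                if stall >= plateau_patience:
                    break
    return model, history


def centralized_train(
    data: LabeledImages,
    arch: ArchitectureConfig,
    epochs: int,
    batch_size: int = 64,
    lr: float = 0.001,
    seed: int = 42,
) -> tuple[NetworkModel, list[float]]:
    """Single-site baseline under the identical optimizer/loss; deterministic
    under ``seed`` (which drives both initialization and batch order via the
    same derivation as round 0 of the federated run)."""
    model = build_network(arch, seed=seed)
    losses = sgd_train(
        model, data.images, data.labels,
        epochs=epochs, batch_size=batch_size, lr=lr,
        seed=round_seed(seed, 0, 0),
    )
    return model, losses


def history_to_rows(history: list[RoundRecord]) -> list[dict]:
    """Flatten round records for CSV export: one row per (round, client)."""
    rows = []
    for rec in history:
        for client_id, trace in enumerate(rec.client_losses):
            rows.append({
                "round": rec.round_index,
                "client_id": client_id,
                "mean_loss": float(np.mean(trace)) if trace else float("nan"),
                "global_accuracy": rec.global_accuracy,
                "global_f1": rec.global_f1,
            })
    return rows
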