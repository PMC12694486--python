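"""Classification evaluation, multi-seed statistics and the combined
performance + explainability model-selection report.

Precision/recall/F1 are support-weighted across the four classes, under which
weighted recall coincides with accuracy. Multi-seed summaries use the sample
standard deviation (n-1) and Student-t 95% confidence intervals with n-1
degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .config import CLASS_NAMES, N_CLASSES, ArchitectureConfig, FederatedConfig
from .data import LabeledImages
from .nn.network import NetworkModel

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray  # row-normalized 4x4


def evaluate_classification(model: NetworkModel, testset: LabeledImages) -> EvalReport:
    preds = model.predict(testset.images)
    return classification_report_from_preds(testset.labels, preds)


def classification_report_from_preds(labels: np.ndarray, preds: np.ndarray) -> EvalReport:
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes yield 0-division warnings
        prec, rec, f1, _ = precision_recall_fscore_support(
            labels, preds, labels=range(N_CLASSES), average="weighted",
            zero_division=0,
        )
    return EvalReport(
        accuracy=float(np.mean(labels == preds)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        confusion=confusion_matrix(labels, preds),
    )


def confusion_matrix(labels: np.ndarray, preds: np.ndarray) -> np.ndarray:
    """Row-normalized 4x4 confusion matrix; a class absent from ``labels``
    yields an all-zero row (with a logged warning)."""
    counts = _sk_confusion(labels, preds, labels=range(N_CLASSES)).astype(np.float64)
    row_sums = counts.sum(axis=1, keepdims=True)
    empty = row_sums[:, 0] == 0
    if empty.any():
        logger.warning("confusion_matrix: no samples for class(es) %s",
                       [CLASS_NAMES[i] for i in np.flatnonzero(empty)])
    with np.errstate(invalid="ignore"):
        normalized = np.where(row_sums > 0, counts / row_sums, 0.0)
    return normalized


@dataclass
class SeedStats:
    values: list[float]
    mean: float = field(init=False)
    std: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        self.mean = float(v.mean())
        if len(v) < 2:
            self.std = 0.0
            self.ci95 = (self.mean, self.mean)
        else:
            self.std = float(v.std(ddof=1))
            self.ci95 = ci_from_summary(self.mean, self.std, len(v))


def multiseed_stats(values: list[float]) -> SeedStats:
    """Mean, sample std and Student-t 95% CI of per-seed metric values."""
    if len(values) == 0:
        raise ValueError("need at least one value")
    return SeedStats(values=list(values))


def ci_from_summary(mean: float, std: float, n: int) -> tuple[float, float]:
    """95% CI: mean +/- t_{0.975, n-1} * std / sqrt(n)."""
    if n < 2:
        return (mean, mean)
    if std == 0:
        return (mean, mean)
    half = float(stats.t.ppf(0.975, n - 1)) * std / np.sqrt(n)
    return (mean - half, mean + half)


def client_scaling_sweep(
    data: LabeledImages,
    arch: ArchitectureConfig,
    cfg: FederatedConfig,
    client_counts: tuple[int, ...] = (3, 6, 9, 15),
    testset: LabeledImages | None = None,
) -> pd.DataFrame:
    """Federated accuracy for each client count, plus mean/std rows (sample std)."""
    from dataclasses import replace

    from .federated import run_federated

    rows = []
    for n_clients in client_counts:
        model, _ = run_federated(data, arch, replace(cfg, n_clients=n_clients),
                                 testset=testset)
        eval_on = testset if testset is not None else data
        report = evaluate_classification(model, eval_on)
        rows.append({"clients": n_clients, "accuracy": report.accuracy})
    df = pd.DataFrame(rows)
    accs = df["accuracy"].to_numpy()
    summary = pd.DataFrame([
        {"clients": "mean", "accuracy": float(accs.mean())},
        {"clients": "std", "accuracy": float(accs.std(ddof=1))},
    ])
    return pd.concat([df, summary], ignore_index=True)


#: metrics where larger is better / smaller is better, as grouped on the
#: two-panel radar comparison
HIGHER_BETTER = ("original_confidence", "iauc", "ad", "ic", "ada")
LOWER_BETTER = ("dauc", "active_pixels", "accuracy_after_masking")


def xai_composite(macro: dict[str, float]) -> float:
    """Declared explanation-quality composite: IAUC + IC + ADA - DAUC - active pixels."""
    return (macro["iauc"] + macro["ic"] + macro["ada"]
            - macro["dauc"] - macro["active_pixels"])


def model_selection_report(
    eval_reports: dict[str, list[EvalReport]],
    xai_reports: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Joint performance + macro-XAI table, ranked lexicographically by mean
    accuracy then by the explanation composite (documented in the output).

    ``eval_reports`` maps candidate name -> per-test-set EvalReports;
    ``xai_reports`` maps candidate name -> macro metric row.
    """
    rows = []
    for name, reports in eval_reports.items():
        macro = xai_reports[name]
        row = {
            "model": name,
            "mean_accuracy": float(np.mean([r.accuracy for r in reports])),
            "mean_f1": float(np.mean([r.f1 for r in reports])),
            "xai_composite": xai_composite(macro),
        }
        for key in HIGHER_BETTER:
            row[f"{key} (higher better)"] = macro[key]
        for key in LOWER_BETTER:
            row[f"{key} (lower better)"] = macro[key]
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["mean_accuracy", "xai_composite"], ascending=False, kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.attrs["ranking_rule"] = (
        "lexicographic: mean accuracy across test sets, ties broken by "
        "xai_composite = iauc + ic + ada - dauc - active_pixels (macro)"
    )
    return df
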