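"""Binary-classification reporting: confusion matrix, five measures, splits.

Reports carry per-class one-vs-rest accuracy, sensitivity, specificity,
F-score and Matthews correlation coefficient (MCC), plus an average row —
all in percent (MCC x100), rounded half-up to two decimals.  In a
two-class problem the table obeys exact symmetries: accuracy and MCC are
identical for both class rows, and each class's sensitivity equals the
other's specificity; the average row is the arithmetic mean of the class
rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "EvalReport",
    "round_half_up",
    "confusion_from_labels",
    "compute_report",
    "split_dataset",
]

CLASS_NAMES = ("benign", "malignant")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike numpy's banker's rounding."""
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; rows = truth (benign, malignant), columns = predicted."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2, 2):
            raise ParameterError(f"expected a 2x2 matrix, got {counts.shape}")
        if counts.min() < 0 or counts.sum() == 0:
            raise ParameterError("counts must be non-negative with a positive total")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_labels(truth, predictions) -> ConfusionMatrix:
    truth = np.asarray(truth, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if truth.shape != predictions.shape or truth.size == 0:
        raise ParameterError("truth and predictions must be equal-length and non-empty")
    counts = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(truth, predictions):
        counts[t, p] += 1
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    mcc: float
    degenerate: bool = False

    def as_tuple(self):
        return (self.accuracy, self.sensitivity, self.specificity,
                self.f_score, self.mcc)


@dataclass(frozen=True)
class EvalReport:
    """Tables-style evaluation block: one row per class plus the average."""

    per_class: dict[str, ClassMetrics]
    average: ClassMetrics
    split: str = ""
    phase: str = ""

    def to_markdown(self) -> str:
        lines = [
            f"| Class | Accuracy | Sensitivity | Specificity | F-Score | MCC |",
            "|---|---|---|---|---|---|",
        ]
        for name, m in {**self.per_class, "average": self.average}.items():
            cells = " | ".join(f"{v:.2f}" for v in m.as_tuple())
            lines.append(f"| {name.capitalize()} | {cells} |")
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        rows = {name: m.as_tuple() for name, m in self.per_class.items()}
        rows["average"] = self.average.as_tuple()
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["accuracy", "sensitivity", "specificity", "f_score", "mcc"],
        )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_report(cm: ConfusionMatrix, round_decimals: int = 2,
                   split: str = "", phase: str = "") -> EvalReport:
    """Per-class and average metrics from a confusion matrix (percent scale).

    Degenerate denominators (an empty truth row or predicted column) yield
    0 for the affected measure and set the row's ``degenerate`` flag — no
    division error escapes.
    """
    c = cm.counts
    total = cm.total
    per_class: dict[str, ClassMetrics] = {}
    raw: list[tuple[float, ...]] = []
    for k, name in enumerate(CLASS_NAMES):
        tp = c[k, k]
        fn = c[k].sum() - tp
        fp = c[:, k].sum() - tp
        tn = total - tp - fn - fp
        acc = (tp + tn) / total
        sens, d1 = _safe_div(tp, tp + fn)
        spec, d2 = _safe_div(tn, tn + fp)
        f1, d3 = _safe_div(2 * tp, 2 * tp + fp + fn)
        mcc_den = math.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        mcc, d4 = _safe_div(float(tp * tn - fp * fn), mcc_den)
        degenerate = d1 or d2 or d3 or d4
        vals = (100 * acc, 100 * sens, 100 * spec, 100 * f1, 100 * mcc)
        raw.append(vals)
        per_class[name] = ClassMetrics(
            *(round_half_up(v, round_decimals) for v in vals), degenerate
        )
    avg_raw = tuple(np.mean(col) for col in zip(*raw))
    average = ClassMetrics(
        *(round_half_up(v, round_decimals) for v in avg_raw),
        any(m.degenerate for m in per_class.values()),
    )
    return EvalReport(per_class, average, split, phase)


def split_dataset(labels, ratio: str = "80:20", stratified: bool = True,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test split.

    ``ratio`` is ``"80:20"`` or ``"70:30"``.  The per-class test count is
    ``floor(test_fraction * n_class)``; the remainder goes to training.
    The returned index arrays are disjoint and exhaustive.
    """
    if ratio not in ("80:20", "70:30"):
        raise ParameterError(f"unsupported ratio {ratio!r}")
    test_frac = int(ratio.split(":")[1]) / 100.0
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    classes = np.unique(labels) if stratified else np.array([None])
    for cls in classes:
        idx = np.flatnonzero(labels == cls) if cls is not None else np.arange(labels.size)
        if idx.size < 2:
            raise ParameterError(f"class {cls!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_test = int(math.floor(test_frac * idx.size))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))
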