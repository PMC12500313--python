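"""Detection-quality harness.

Compares per-frame *true* class sets against *predicted* class sets
(frame-level set membership — the granularity at which the guidance
engine actually consumes detections, not bbox-level matching).  Reports
per-step micro-averaged precision/recall/F1, a per-class TP/FP/FN
confusion table, and the cumulative summary: mean and SD of the
per-step precision and recall across task steps.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import TaskModule

__all__ = [
    "FrameLabelPair",
    "DetectionEvalReport",
    "evaluate_detections",
    "confusion_matrix",
    "read_label_pairs",
    "write_label_pairs",
]


@dataclass(frozen=True)
class FrameLabelPair:
    timestamp_ms: float
    true_classes: frozenset[str]
    predicted_classes: frozenset[str]
    step_id: str


@dataclass
class DetectionEvalReport:
    per_step: dict[str, dict[str, Optional[float]]]
    cumulative_precision: tuple[Optional[float], Optional[float]]  # (mean, sd)
    cumulative_recall: tuple[Optional[float], Optional[float]]
    confusion: pd.DataFrame  # columns: class, tp, fp, fn

    def to_dict(self) -> dict:
        return {
            "per_step": self.per_step,
            "cumulative_precision": {
                "mean": self.cumulative_precision[0],
                "sd": self.cumulative_precision[1],
            },
            "cumulative_recall": {
                "mean": self.cumulative_recall[0],
                "sd": self.cumulative_recall[1],
            },
            "confusion": self.confusion.to_dict(orient="records"),
        }


def confusion_matrix(pairs: Sequence[FrameLabelPair]) -> pd.DataFrame:
    """Per-class TP/FP/FN counts over all frames.

    TP: class in both sets; FP: predicted only; FN: true only.  Counts
    are additive over concatenated pair lists.
    """
    if not pairs:
        raise ValueError("confusion_matrix requires at least one frame pair")
    counts: dict[str, list[int]] = {}

    def bump(cls: str, slot: int) -> None:
        counts.setdefault(cls, [0, 0, 0])[slot] += 1

    for pair in pairs:
        for cls in pair.true_classes & pair.predicted_classes:
            bump(cls, 0)
        for cls in pair.predicted_classes - pair.true_classes:
            bump(cls, 1)
        for cls in pair.true_classes - pair.predicted_classes:
            bump(cls, 2)
    rows = [
        {"class": cls, "tp": c[0], "fp": c[1], "fn": c[2]}
        for cls, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["class", "tp", "fp", "fn"])


def _mean_sd(values: list[float], population: bool) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return (None, None)
    mean = sum(values) / len(values)
    ddof = 0 if population else 1
    if len(values) - ddof <= 0:
        return (mean, 0.0 if population else None)
    var = sum((v - mean) ** 2 for v in values) / (len(values) - ddof)
    return (mean, math.sqrt(var))


def evaluate_detections(
    pairs: Sequence[FrameLabelPair],
    module: Optional[TaskModule] = None,
    population_sd: bool = True,
) -> DetectionEvalReport:
    """Per-step micro-averaged precision/recall/F1 and the cumulative
    (mean, SD across steps) summary.

    Per step, over all frames assigned to it: precision = TP/(TP+FP),
    recall = TP/(TP+FN) on class-set membership.  A step with a zero
    denominator reports None for that metric and is excluded from the
    cumulative mean/SD with a warning.  SD is the population SD by
    default (``population_sd=False`` for the sample SD).
    """
    if not pairs:
        raise ValueError("evaluate_detections requires at least one frame pair")
    if module is not None:
        known = {s.step_id for s in module.steps}
        bad = sorted({p.step_id for p in pairs} - known)
        if bad:
            raise ValueError(f"pairs reference step ids not in module: {bad}")
        step_order = [s.step_id for s in module.steps]
    else:
        step_order = list(dict.fromkeys(p.step_id for p in pairs))

    per_step: dict[str, dict[str, Optional[float]]] = {}
    precisions, recalls = [], []
    for step_id in step_order:
        step_pairs = [p for p in pairs if p.step_id == step_id]
        if not step_pairs:
            continue
        tp = sum(len(p.true_classes & p.predicted_classes) for p in step_pairs)
        fp = sum(len(p.predicted_classes - p.true_classes) for p in step_pairs)
        fn = sum(len(p.true_classes - p.predicted_classes) for p in step_pairs)
        precision = tp / (tp + fp) if tp + fp > 0 else None
        recall = tp / (tp + fn) if tp + fn > 0 else None
        if precision is None:
            warnings.warn(
                f"step {step_id!r}: no predictions; precision undefined, "
                "excluded from cumulative summary"
            )
        else:
            precisions.append(precision)
        if recall is None:
            warnings.warn(
                f"step {step_id!r}: no true classes; recall undefined, "
                "excluded from cumulative summary"
            )
        else:
            recalls.append(recall)
        if precision is not None and recall is not None and precision + recall > 0:
            f1: Optional[float] = 2 * precision * recall / (precision + recall)
        else:
            f1 = None
        per_step[step_id] = {"precision": precision, "recall": recall, "f1": f1}

    return DetectionEvalReport(
        per_step=per_step,
        cumulative_precision=_mean_sd(precisions, population_sd),
        cumulative_recall=_mean_sd(recalls, population_sd),
        confusion=confusion_matrix(pairs),
    )


def write_label_pairs(pairs: Iterable[FrameLabelPair], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                json.dumps(
                    {
                        "timestamp_ms": p.timestamp_ms,
                        "true_classes": sorted(p.true_classes),
                        "predicted_classes": sorted(p.predicted_classes),
                        "step_id": p.step_id,
                    }
                )
                + "\n"
            )
            n += 1
    return n


def read_label_pairs(path: str | Path) -> list[FrameLabelPair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            pairs.append(
                FrameLabelPair(
                    timestamp_ms=d["timestamp_ms"],
                    true_classes=frozenset(d["true_classes"]),
                    predicted_classes=frozenset(d["predicted_classes"]),
                    step_id=d["step_id"],
                )
            )
    return pairs
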