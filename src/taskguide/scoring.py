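"""The three clinical scoring instruments.

* **Daily Task Completion Test** — each task step earns 2 points when
  performed fully correctly (completed with no error events, within its
  time limit), 1 point when partially incorrect (completed but with a
  corrective event or over time), and 0 when incorrect (not completed,
  or assistance escalated to the assessor performing the step).  The
  default six-step module has a perfect score of 12.

* **Modified EFPT** — the simple-cooking adaptation of the Executive
  Function Performance Test.  Each scored component (a configurable
  grouping of task steps, five by default) is graded 0–5 by the highest
  assistance level reached on any of its member steps: 0 no cue, 1
  verbal, 2 gestural, 3 direct verbal, 4 physical, 5 performed by the
  assessor.  Totals range 0–25; higher means greater executive
  dysfunction.

* **SUS** — the 10-item System Usability Scale with the standard
  odd/even transformation, score = 2.5 * [sum_odd(item-1) +
  sum_even(5-item)], banded as: <50 significant usability issues,
  [50, 68) marginal, [68, 80] acceptable, >80 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import TaskModule
from .engine import SessionRecord

__all__ = [
    "CompletionScore",
    "EFPTScore",
    "SUSResult",
    "SUS_BANDS",
    "ScoringError",
    "score_completion",
    "score_efpt",
    "score_sus",
    "classify_sus",
    "read_sus_responses",
    "score_sus_table",
]

SUS_BANDS = ("significant_issues", "marginal", "acceptable", "excellent")


class ScoringError(ValueError):
    """A record/module contract violation during scoring."""


@dataclass(frozen=True)
class CompletionScore:
    per_step: dict[str, int]
    total: int


@dataclass(frozen=True)
class EFPTScore:
    per_component: dict[str, int]
    total: int


@dataclass(frozen=True)
class SUSResult:
    item_scores: tuple[int, ...]
    score: float
    band: str


def score_completion(record: SessionRecord, module: TaskModule) -> CompletionScore:
    """Daily Task Completion Test: 0/1/2 per step, summed.

    Pure function of the record; never mutates it.
    """
    if set(record.step_timings) != {s.step_id for s in module.steps}:
        raise ScoringError(
            "record step ids do not match the module "
            f"({sorted(record.step_timings)} vs {[s.step_id for s in module.steps]})"
        )
    rules = module.completion_rules
    per_step: dict[str, int] = {}
    for step in module.steps:
        timing = record.step_timings[step.step_id]
        cue = record.max_cue_level.get(step.step_id, 0)
        errors = record.error_count.get(step.step_id, 0)
        if not timing.completed or cue >= rules.assessor_cue_level:
            points = 0
        else:
            overtime = (
                timing.duration_s is not None
                and timing.duration_s > step.time_limit_s
            )
            degraded = (rules.error_downgrades and errors > 0) or (
                rules.overtime_downgrades and overtime
            )
            points = 1 if degraded else 2
        per_step[step.step_id] = points
    return CompletionScore(per_step=per_step, total=sum(per_step.values()))


def score_efpt(record: SessionRecord, module: TaskModule) -> EFPTScore:
    """Modified EFPT: per component, the worst (max) cue level reached
    on any member step; totals 0 to 5 * number of components."""
    known = {s.step_id for s in module.steps}
    per_component: dict[str, int] = {}
    for comp in module.efpt_components:
        for sid in comp.member_step_ids:
            if sid not in known:
                raise ScoringError(
                    f"EFPT component {comp.component_id!r} references "
                    f"unknown step {sid!r}"
                )
        per_component[comp.component_id] = max(
            record.max_cue_level.get(sid, 0) for sid in comp.member_step_ids
        )
    return EFPTScore(per_component=per_component, total=sum(per_component.values()))


def classify_sus(score: float) -> str:
    """Band a SUS score: <50 significant issues, [50, 68) marginal,
    [68, 80] acceptable, strictly above 80 excellent."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"SUS score {score} outside [0, 100]")
    if score < 50.0:
        return "significant_issues"
    if score < 68.0:
        return "marginal"
    if score <= 80.0:
        return "acceptable"
    return "excellent"


def score_sus(item_scores: Sequence[int]) -> SUSResult:
    """Score one 10-item SUS response (items 1..5 each).

    Odd items are positively worded (contribute item-1), even items
    negatively (contribute 5-item); the sum is scaled by 2.5 onto
    [0, 100], always a multiple of 2.5.  Missing or out-of-range items
    are a validation error — no imputation.
    """
    items = list(item_scores)
    if len(items) != 10:
        raise ValueError(f"SUS needs exactly 10 items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not isinstance(v, (int,)) or isinstance(v, bool) or not 1 <= v <= 5:
            raise ValueError(f"SUS item {i} must be an integer in 1..5, got {v!r}")
    raw = sum(v - 1 for v in items[0::2]) + sum(5 - v for v in items[1::2])
    score = 2.5 * raw
    return SUSResult(item_scores=tuple(items), score=score, band=classify_sus(score))


def read_sus_responses(path: str | Path) -> pd.DataFrame:
    """Read SUS responses from CSV with columns participant_id,
    item_1..item_10."""
    df = pd.read_csv(path)
    expected = ["participant_id"] + [f"item_{i}" for i in range(1, 11)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SUS columns {missing}")
    return df[expected]


def score_sus_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Score a table of SUS responses; returns participant_id,
    sus_score, band."""
    rows = []
    for _, row in responses.iterrows():
        result = score_sus([int(row[f"item_{i}"]) for i in range(1, 11)])
        rows.append(
            {
                "participant_id": row["participant_id"],
                "sus_score": result.score,
                "band": result.band,
            }
        )
    return pd.DataFrame(rows)
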