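"""The guidance state machine.

``run_session`` replays a detection-frame stream against a task module
and produces a complete, deterministic event log.  Steps are attempted
strictly in order.  The engine smooths per-class presence with the
module's rolling window, then on each smoothed state:

1. **Errors first.**  Each error condition keeps a consecutive-hold
   counter; when it reaches the condition's dwell requirement the error
   fires once (``error_detected``, plus ``corrective_shown`` in assisted
   mode), increments the step's error count, resets the completion dwell
   counter, and stays latched until the condition breaks for a frame.
   An error firing on the same state as a would-be completion wins.
2. **Completion.**  The step completes when its completion condition
   holds on ``dwell_frames`` consecutive smoothed states
   (``step_completed``, plus ``positive_feedback`` — the on-screen
   "great" — in assisted mode), and the next step's instruction is
   issued at the same timestamp.
3. **Cue escalation.**  While a step stalls, cue levels 1..5 are reached
   at their configured stall timeouts (measured from the step's
   instruction).  Assisted sessions emit ``cue_issued`` events;
   unassisted sessions run the identical machine and record the reached
   level silently, so the modified EFPT is computable for both study
   conditions.  Reaching level 5 marks the step as performed by the
   assessor (not completed) and force-advances to the next step.

Timing capture: per-step initiation time (instruction to first
hand-present frame), per-step duration (instruction to completion), and
total completion time (first instruction to session end), all in
seconds.  If the stream ends mid-task the remaining steps are marked
incomplete and the total time is undefined — never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .config import StepCondition, TaskModule
from .detection import (
    DEFAULT_PRESENCE_THRESHOLD,
    Frame,
    RollingSmoother,
    SmoothedState,
    spatial_predicate_holds,
)

__all__ = [
    "EngineParams",
    "SessionEvent",
    "StepTiming",
    "SessionRecord",
    "EVENT_KINDS",
    "run_session",
    "compute_timings",
    "condition_holds",
]

EVENT_KINDS = (
    "instruction_shown",
    "step_completed",
    "error_detected",
    "corrective_shown",
    "cue_issued",
    "positive_feedback",
    "session_end",
)


@dataclass(frozen=True)
class EngineParams:
    """Tunable engine thresholds.

    ``presence_threshold``: inclusive smoothed-score cutoff for a class
    to count as present (default 0.5).  ``binary_presence``: smooth
    detected/not-detected flags instead of confidences.
    """

    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    binary_presence: bool = False


@dataclass(frozen=True)
class SessionEvent:
    timestamp_ms: float
    kind: str
    step_id: str
    cue_level: Optional[int] = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if (self.cue_level is not None) != (self.kind == "cue_issued"):
            raise ValueError("cue_level must be present iff kind is cue_issued")


@dataclass
class StepTiming:
    initiation_time_s: Optional[float] = None
    duration_s: Optional[float] = None
    completed: bool = False


@dataclass
class SessionRecord:
    session_id: str
    participant_id: str
    assisted: bool
    module_id: str
    events: list[SessionEvent] = field(default_factory=list)
    step_timings: dict[str, StepTiming] = field(default_factory=dict)
    max_cue_level: dict[str, int] = field(default_factory=dict)
    error_count: dict[str, int] = field(default_factory=dict)
    total_completion_time_s: Optional[float] = None

    @property
    def completed(self) -> bool:
        """True when every step was resolved (completed or taken over)."""
        return self.total_completion_time_s is not None

    def events_of_kind(self, kind: str) -> list[SessionEvent]:
        return [e for e in self.events if e.kind == kind]


def condition_holds(
    condition: StepCondition,
    state: SmoothedState,
    frame: Frame,
    threshold: float,
) -> bool:
    """A condition holds on a smoothed state when all required classes
    are at/above the presence threshold, all forbidden classes below it,
    and every spatial predicate holds on the raw frame's detections."""
    for c in condition.required_present:
        if state.presence.get(c, 0.0) < threshold:
            return False
    for c in condition.required_absent:
        if state.presence.get(c, 0.0) >= threshold:
            return False
    for pred in condition.spatial_predicates:
        if not spatial_predicate_holds(pred, frame):
            return False
    return True


class _StepState:
    """Mutable per-step tracking while the step is active."""

    def __init__(self, n_error_conditions: int) -> None:
        self.activation_ms: Optional[float] = None
        self.dwell = 0
        self.err_counters = [0] * n_error_conditions
        self.err_latched = [False] * n_error_conditions
        self.issued_levels: set[int] = set()


def run_session(
    module: TaskModule,
    frames: Iterable[Frame],
    assisted: bool = True,
    params: EngineParams = EngineParams(),
    session_id: str = "session",
    participant_id: str = "anonymous",
) -> SessionRecord:
    """Replay a frame stream through the guidance state machine.

    Deterministic: identical module, stream, and parameters produce
    byte-identical event logs.  The same stream yields identical
    step-condition satisfaction times whether assisted or not; only the
    feedback/cue events emitted differ.
    """
    record = SessionRecord(
        session_id=session_id,
        participant_id=participant_id,
        assisted=assisted,
        module_id=module.module_id,
    )
    steps = module.steps
    for s in steps:
        record.step_timings[s.step_id] = StepTiming()
        record.max_cue_level[s.step_id] = 0
        record.error_count[s.step_id] = 0

    smoother = RollingSmoother(
        module.smoothing_window, module.class_vocabulary, params.binary_presence
    )
    threshold = params.presence_threshold

    idx = 0
    state_track = _StepState(len(steps[0].error_conditions))
    first_instruction_ms: Optional[float] = None
    last_ts: Optional[float] = None
    done = False

    def emit(ts: float, kind: str, step_id: str, cue_level=None, detail="") -> None:
        record.events.append(SessionEvent(ts, kind, step_id, cue_level, detail))

    def activate(ts: float) -> None:
        nonlocal first_instruction_ms
        step = steps[idx]
        state_track.activation_ms = ts
        emit(ts, "instruction_shown", step.step_id, detail=step.instruction_text)
        if first_instruction_ms is None:
            first_instruction_ms = ts

    def advance(ts: float) -> bool:
        """Move to the next step; returns True when the session ended."""
        nonlocal idx, state_track
        idx += 1
        if idx < len(steps):
            state_track = _StepState(len(steps[idx].error_conditions))
            activate(ts)
            return False
        emit(ts, "session_end", steps[-1].step_id, detail="all steps resolved")
        return True

    for frame in frames:
        if last_ts is not None and frame.timestamp_ms <= last_ts:
            raise ValueError(
                f"frame timestamps not strictly increasing at {frame.timestamp_ms}"
            )
        last_ts = frame.timestamp_ms
        smoothed = smoother.push(frame)
        if done:
            continue

        step = steps[idx]
        timing = record.step_timings[step.step_id]
        if state_track.activation_ms is None:
            activate(frame.timestamp_ms)

        if (
            timing.initiation_time_s is None
            and frame.hand_present
            and frame.timestamp_ms >= state_track.activation_ms
        ):
            timing.initiation_time_s = (
                frame.timestamp_ms - state_track.activation_ms
            ) / 1000.0

        # 1. errors (fire once per episode; error wins ties with completion)
        error_fired = False
        for j, err in enumerate(step.error_conditions):
            holds = condition_holds(err.condition, smoothed, frame, threshold)
            if holds:
                state_track.err_counters[j] += 1
                if (
                    state_track.err_counters[j] >= err.condition.dwell_frames
                    and not state_track.err_latched[j]
                ):
                    state_track.err_latched[j] = True
                    error_fired = True
                    record.error_count[step.step_id] += 1
                    emit(frame.timestamp_ms, "error_detected", step.step_id)
                    if assisted:
                        emit(
                            frame.timestamp_ms,
                            "corrective_shown",
                            step.step_id,
                            detail=err.corrective_instruction,
                        )
            else:
                state_track.err_counters[j] = 0
                state_track.err_latched[j] = False

        # 2. completion dwell
        if error_fired:
            state_track.dwell = 0
        elif condition_holds(step.completion_condition, smoothed, frame, threshold):
            state_track.dwell += 1
        else:
            state_track.dwell = 0

        if state_track.dwell >= step.completion_condition.dwell_frames:
            timing.completed = True
            timing.duration_s = (
                frame.timestamp_ms - state_track.activation_ms
            ) / 1000.0
            emit(frame.timestamp_ms, "step_completed", step.step_id)
            if assisted:
                emit(
                    frame.timestamp_ms,
                    "positive_feedback",
                    step.step_id,
                    detail="great",
                )
            done = advance(frame.timestamp_ms)
            continue

        # 3. cue escalation on stall
        elapsed_s = (frame.timestamp_ms - state_track.activation_ms) / 1000.0
        taken_over = False
        for level in sorted(step.cue_schedule):
            if level in state_track.issued_levels:
                continue
            if elapsed_s >= step.cue_schedule[level].timeout_s:
                state_track.issued_levels.add(level)
                record.max_cue_level[step.step_id] = max(
                    record.max_cue_level[step.step_id], level
                )
                if assisted:
                    emit(
                        frame.timestamp_ms,
                        "cue_issued",
                        step.step_id,
                        cue_level=level,
                        detail=step.cue_schedule[level].text,
                    )
                if level == 5:
                    taken_over = True
        if taken_over:
            # assessor performs the step: not completed, but task moves on
            done = advance(frame.timestamp_ms)

    if not done and last_ts is not None:
        active = steps[idx].step_id if idx < len(steps) else steps[-1].step_id
        emit(last_ts, "session_end", active, detail="stream exhausted")
    if done and first_instruction_ms is not None:
        record.total_completion_time_s = (
            record.events[-1].timestamp_ms - first_instruction_ms
        ) / 1000.0
    return record


def write_session(record: SessionRecord, path) -> None:
    """Serialize a session as JSON lines: a header object, then one
    event per line."""
    import json

    header = {
        "session_id": record.session_id,
        "participant_id": record.participant_id,
        "assisted": record.assisted,
        "module_id": record.module_id,
        "step_timings": {
            sid: {
                "initiation_time_s": t.initiation_time_s,
                "duration_s": t.duration_s,
                "completed": t.completed,
            }
            for sid, t in record.step_timings.items()
        },
        "max_cue_level": record.max_cue_level,
        "error_count": record.error_count,
        "total_completion_time_s": record.total_completion_time_s,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps({"session": header}) + "\n")
        for e in record.events:
            fh.write(
                json.dumps(
                    {
                        "timestamp_ms": e.timestamp_ms,
                        "kind": e.kind,
                        "step_id": e.step_id,
                        "cue_level": e.cue_level,
                        "detail": e.detail,
                    }
                )
                + "\n"
            )


def read_session(path) -> SessionRecord:
    """Inverse of :func:`write_session`."""
    import json

    with open(path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    if not lines or "session" not in lines[0]:
        raise ValueError(f"{path}: missing session header line")
    h = lines[0]["session"]
    record = SessionRecord(
        session_id=h["session_id"],
        participant_id=h["participant_id"],
        assisted=h["assisted"],
        module_id=h["module_id"],
        step_timings={
            sid: StepTiming(**t) for sid, t in h["step_timings"].items()
        },
        max_cue_level={k: int(v) for k, v in h["max_cue_level"].items()},
        error_count={k: int(v) for k, v in h["error_count"].items()},
        total_completion_time_s=h["total_completion_time_s"],
    )
    for d in lines[1:]:
        record.events.append(
            SessionEvent(
                d["timestamp_ms"], d["kind"], d["step_id"], d["cue_level"], d["detail"]
            )
        )
    return record


def compute_timings(record: SessionRecord) -> pd.DataFrame:
    """Per-step timing summary plus a totals row, in seconds.

    Columns: step_id, completed, initiation_s, duration_s, errors,
    max_cue_level.  Steps with no hand ever present report a missing
    initiation time (NaN), never 0.  Requires that the session showed at
    least one instruction.
    """
    if not record.events_of_kind("instruction_shown"):
        raise ValueError("record has no instruction events; nothing to time")
    rows = []
    for step_id, timing in record.step_timings.items():
        rows.append(
            {
                "step_id": step_id,
                "completed": timing.completed,
                "initiation_s": timing.initiation_time_s,
                "duration_s": timing.duration_s,
                "errors": record.error_count.get(step_id, 0),
                "max_cue_level": record.max_cue_level.get(step_id, 0),
            }
        )
    rows.append(
        {
            "step_id": "__total__",
            "completed": record.completed,
            "initiation_s": None,
            "duration_s": record.total_completion_time_s,
            "errors": sum(record.error_count.values()),
            "max_cue_level": max(record.max_cue_level.values(), default=0),
        }
    )
    df = pd.DataFrame(rows)
    for col in ("initiation_s", "duration_s"):
        df[col] = pd.to_numeric(df[col])  # missing timings become NaN
    return df
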