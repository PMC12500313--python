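"""Independent reference implementations used as test oracles.

``naive_run_session`` is a deliberately simple quadratic-time replay
interpreter: for every step it rescans the stream and recomputes the
rolling average by materializing each window from the raw frames.  It
shares no code with the engine's incremental smoother or state machine
beyond the public data types, so agreement between the two is evidence
the engine implements the declared semantics.

``random_module``/``random_stream`` generate arbitrary small task
modules and detection streams for the equivalence suites.
"""

from __future__ import annotations

import numpy as np

from taskguide.config import (
    CueLevel,
    ErrorCondition,
    SpatialPredicate,
    StepCondition,
    TaskModule,
    TaskStep,
)
from taskguide.detection import Frame, ObjectDetection
from taskguide.engine import EngineParams, SessionEvent, SessionRecord, StepTiming


def brute_presence(
    frames: list[Frame],
    k: int,
    window: int,
    vocabulary: set[str],
    binary: bool,
) -> dict[str, float]:
    """Rolling-average presence at frame k by materializing the window."""
    chunk = frames[max(0, k - window + 1) : k + 1]
    presence: dict[str, float] = {}
    for cls in vocabulary:
        total = 0.0
        for f in chunk:
            best = 0.0
            for det in f.detections:
                if det.class_label == cls:
                    v = 1.0 if binary else det.confidence
                    if v > best:
                        best = v
            total += best
        if total > 0:
            presence[cls] = total / len(chunk)
    return presence


def _naive_best(frame: Frame, cls: str):
    best = None
    for det in frame.detections:
        if det.class_label != cls:
            continue
        key = (-det.confidence, det.bbox[0], det.bbox[1])
        if best is None or key < best[0]:
            best = (key, det)
    return None if best is None else best[1]


def _naive_spatial(pred: SpatialPredicate, frame: Frame) -> bool:
    s = _naive_best(frame, pred.subject)
    o = _naive_best(frame, pred.object_)
    if s is None or o is None:
        return False
    sx, sy, sw, sh = s.bbox
    ox, oy, ow, oh = o.bbox
    scx, scy = sx + sw / 2, sy + sh / 2
    ocx, ocy = ox + ow / 2, oy + oh / 2
    if pred.relation == "contains":
        return ox <= scx <= ox + ow and oy <= scy <= oy + oh
    if pred.relation == "overlaps":
        ix = max(0.0, min(sx + sw, ox + ow) - max(sx, ox))
        iy = max(0.0, min(sy + sh, oy + oh) - max(sy, oy))
        return ix * iy > 0.0
    if pred.relation == "above":
        return scy < ocy
    raise ValueError(pred.relation)


def naive_run_session(
    module: TaskModule,
    frames: list[Frame],
    assisted: bool,
    params: EngineParams = EngineParams(),
    session_id: str = "session",
    participant_id: str = "anonymous",
) -> SessionRecord:
    """Quadratic-time replay: rescans the stream once per step."""
    frames = list(frames)
    vocab = module.class_vocabulary
    record = SessionRecord(session_id, participant_id, assisted, module.module_id)
    for s in module.steps:
        record.step_timings[s.step_id] = StepTiming()
        record.max_cue_level[s.step_id] = 0
        record.error_count[s.step_id] = 0

    def holds(cond: StepCondition, pres: dict[str, float], frame: Frame) -> bool:
        if any(pres.get(c, 0.0) < params.presence_threshold for c in cond.required_present):
            return False
        if any(pres.get(c, 0.0) >= params.presence_threshold for c in cond.required_absent):
            return False
        return all(_naive_spatial(p, frame) for p in cond.spatial_predicates)

    events: list[SessionEvent] = []
    first_instruction = None
    k = 0  # index of the next frame to process
    ended = False
    # activation timestamp of the upcoming step: the frame on which the
    # previous step resolved, or the first frame for step 0
    next_activation = frames[0].timestamp_ms if frames else None
    n_resolved = 0
    for step in module.steps:
        activation = next_activation
        events.append(
            SessionEvent(activation, "instruction_shown", step.step_id, None, step.instruction_text)
        )
        if first_instruction is None:
            first_instruction = activation
        timing = record.step_timings[step.step_id]
        dwell = 0
        err_counters = [0] * len(step.error_conditions)
        err_latched = [False] * len(step.error_conditions)
        issued: set[int] = set()
        resolved = False
        while k < len(frames):
            frame = frames[k]
            pres = brute_presence(frames, k, module.smoothing_window, vocab, params.binary_presence)
            if (
                timing.initiation_time_s is None
                and frame.hand_present
                and frame.timestamp_ms >= activation
            ):
                timing.initiation_time_s = (frame.timestamp_ms - activation) / 1000.0
            fired = False
            for j, err in enumerate(step.error_conditions):
                if holds(err.condition, pres, frame):
                    err_counters[j] += 1
                    if err_counters[j] >= err.condition.dwell_frames and not err_latched[j]:
                        err_latched[j] = True
                        fired = True
                        record.error_count[step.step_id] += 1
                        events.append(
                            SessionEvent(frame.timestamp_ms, "error_detected", step.step_id)
                        )
                        if assisted:
                            events.append(
                                SessionEvent(
                                    frame.timestamp_ms,
                                    "corrective_shown",
                                    step.step_id,
                                    None,
                                    err.corrective_instruction,
                                )
                            )
                else:
                    err_counters[j] = 0
                    err_latched[j] = False
            if fired:
                dwell = 0
            elif holds(step.completion_condition, pres, frame):
                dwell += 1
            else:
                dwell = 0
            if dwell >= step.completion_condition.dwell_frames:
                timing.completed = True
                timing.duration_s = (frame.timestamp_ms - activation) / 1000.0
                events.append(SessionEvent(frame.timestamp_ms, "step_completed", step.step_id))
                if assisted:
                    events.append(
                        SessionEvent(frame.timestamp_ms, "positive_feedback", step.step_id, None, "great")
                    )
                k += 1
                resolved = True
                next_activation = frame.timestamp_ms
                break
            elapsed = (frame.timestamp_ms - activation) / 1000.0
            taken_over = False
            for level in sorted(step.cue_schedule):
                if level in issued:
                    continue
                if elapsed >= step.cue_schedule[level].timeout_s:
                    issued.add(level)
                    record.max_cue_level[step.step_id] = max(
                        record.max_cue_level[step.step_id], level
                    )
                    if assisted:
                        events.append(
                            SessionEvent(
                                frame.timestamp_ms,
                                "cue_issued",
                                step.step_id,
                                level,
                                step.cue_schedule[level].text,
                            )
                        )
                    if level == 5:
                        taken_over = True
            if taken_over:
                k += 1
                resolved = True
                next_activation = frame.timestamp_ms
                break
            k += 1
        if resolved:
            n_resolved += 1
        else:
            break
    if n_resolved == len(module.steps):
        events.append(
            SessionEvent(next_activation, "session_end", module.steps[-1].step_id, None, "all steps resolved")
        )
        ended = True
    if not ended and frames:
        active = module.steps[min(n_resolved, len(module.steps) - 1)].step_id
        events.append(
            SessionEvent(frames[-1].timestamp_ms, "session_end", active, None, "stream exhausted")
        )
    record.events = events
    if ended and first_instruction is not None:
        record.total_completion_time_s = (
            events[-1].timestamp_ms - first_instruction
        ) / 1000.0
    return record


CLASSES = [f"c{i}" for i in range(8)]


def random_condition(rng: np.random.Generator, max_dwell: int = 3) -> StepCondition:
    present = list(rng.choice(CLASSES, size=rng.integers(1, 3), replace=False))
    absent = [c for c in rng.choice(CLASSES, size=rng.integers(0, 2), replace=False) if c not in present]
    preds = []
    if rng.random() < 0.25:
        a, b = rng.choice(CLASSES, size=2, replace=False)
        preds.append(
            SpatialPredicate(
                relation=str(rng.choice(["contains", "overlaps", "above"])),
                subject=str(a),
                object=str(b),
            )
        )
    return StepCondition(
        required_present=set(present),
        required_absent=set(absent),
        spatial_predicates=preds,
        dwell_frames=int(rng.integers(1, max_dwell + 1)),
    )


def random_module(rng: np.random.Generator, max_steps: int = 6) -> TaskModule:
    n_steps = int(rng.integers(2, max_steps + 1))
    steps = []
    for i in range(n_steps):
        n_levels = int(rng.integers(0, 6))
        base = float(rng.uniform(1.0, 4.0))
        schedule = {
            lv: CueLevel(timeout_s=base * lv, text=f"cue {lv}")
            for lv in range(1, n_levels + 1)
        }
        n_err = int(rng.integers(0, 3))
        errors = [
            ErrorCondition(
                condition=random_condition(rng, max_dwell=2),
                corrective_instruction=f"fix step {i}",
            )
            for _ in range(n_err)
        ]
        steps.append(
            TaskStep(
                step_id=f"s{i}",
                index=i,
                instruction_text=f"do step {i}",
                completion_condition=random_condition(rng),
                error_conditions=errors,
                time_limit_s=float(rng.uniform(5, 60)),
                cue_schedule=schedule,
            )
        )
    return TaskModule(
        module_id="random",
        name="random",
        steps=steps,
        frame_period_ms=100.0,
        smoothing_window=int(rng.integers(1, 7)),
    )


def random_stream(rng: np.random.Generator, max_frames: int = 250) -> list[Frame]:
    n = int(rng.integers(5, max_frames + 1))
    frames = []
    for k in range(n):
        detections = []
        for cls in CLASSES:
            if rng.random() < 0.35:
                w = float(rng.uniform(0.05, 0.4))
                h = float(rng.uniform(0.05, 0.4))
                x = float(rng.uniform(0, 1 - w))
                y = float(rng.uniform(0, 1 - h))
                detections.append(ObjectDetection(cls, float(rng.uniform(0.05, 1.0)), (x, y, w, h)))
        hand = bool(rng.random() < 0.5)
        frames.append(
            Frame(
                timestamp_ms=k * 100.0,
                detections=detections,
                hand_present=hand,
                hand_centroid=(0.5, 0.5) if hand else None,
            )
        )
    return frames
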