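"""Synthetic participant simulator.

Generates detection-frame streams for parameterized virtual
participants performing a task module, so the whole pipeline — smoother,
state machine, scoring, evaluation — runs end-to-end with no camera and
no trained model.

The behavior model is a semi-Markov script per step: the participant
*hesitates* (log-normal pre-action delay), may enter an *error state*
(Bernoulli per step), and then *acts* for roughly the profile's base
action duration, at which point the scene transitions to the step's
completion state.  While in an error state the participant recovers
with some probability per 5-second check interval: in assisted mode the
probability is the profile's responsiveness to the cue level active at
that elapsed time, in unassisted mode a fixed (lower) self-recovery
probability — unassisted participants do finish, just slower.

Detection noise is applied per frame: per-class false-negative drops,
false-positive insertions from the module vocabulary, and Gaussian
jitter on confidences and bbox coordinates.  Everything is reproducible
from the seed: the same (module, profile, noise, seed) yields
byte-identical streams.  Participant-level draws (hesitations, error
occurrences, action paces) come from a generator keyed by (seed,
profile id) only, so the paired assisted/unassisted sessions of one
virtual participant share them and differ only in condition-dependent
draws (recovery and noise).
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import TaskModule
from .detection import Frame, ObjectDetection
from .engine import EngineParams, SessionRecord, run_session
from .evaluation import FrameLabelPair
from .scoring import score_completion, score_efpt

__all__ = [
    "ParticipantProfile",
    "NoiseModel",
    "GroundTruth",
    "Segment",
    "CohortDataset",
    "simulate_session",
    "simulate_cohort",
    "label_frames",
    "PATIENT_PROFILE",
    "CONTROL_PROFILE",
    "PERFECT_PROFILE",
    "DEFAULT_NOISE",
    "ZERO_NOISE",
    "DEFAULT_FRAME_PERIOD_MS",
]

#: Simulator sampling interval.  The deployed system polled far faster;
#: for desk-scale simulation 100 ms keeps a two-minute session near
#: 1200 frames.  The engine treats the period as data either way.
DEFAULT_FRAME_PERIOD_MS = 100.0

#: How often a participant in an error state gets a chance to recover.
CORRECTION_CHECK_INTERVAL_S = 5.0

#: Hard cap on one error episode, so timelines always terminate.
MAX_ERROR_EPISODE_S = 90.0

#: Quiet tail appended after the last scene transition so the engine's
#: smoothing/dwell latency can drain before the stream ends.
TAIL_S = 15.0


@dataclass(frozen=True)
class ParticipantProfile:
    """Stochastic behavior model of one virtual participant.

    ``per_step_error_prob``: chance of entering the step's error state.
    ``hesitation_log_mean``/``hesitation_log_sd``: log-normal pre-action
    delay, seconds.  ``cue_responsiveness``: per cue level 1..5, the
    probability of resuming correct action within one check interval
    after that cue (must be non-decreasing in level).
    ``base_action_duration_s``: nominal time to physically perform a
    step.  ``unassisted_recovery_prob``: per-interval self-correction
    probability when no device guidance is given.
    """

    profile_id: str
    per_step_error_prob: float
    hesitation_log_mean: float
    hesitation_log_sd: float
    cue_responsiveness: dict[int, float]
    base_action_duration_s: float
    unassisted_recovery_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_step_error_prob <= 1.0:
            raise ValueError("per_step_error_prob must be in [0, 1]")
        if self.hesitation_log_sd < 0:
            raise ValueError("hesitation_log_sd must be >= 0")
        if self.base_action_duration_s <= 0:
            raise ValueError("base_action_duration_s must be > 0")
        if not 0.0 <= self.unassisted_recovery_prob <= 1.0:
            raise ValueError("unassisted_recovery_prob must be in [0, 1]")
        levels = sorted(self.cue_responsiveness)
        probs = [self.cue_responsiveness[lv] for lv in levels]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("cue_responsiveness probabilities must be in [0, 1]")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValueError("cue_responsiveness must be non-decreasing in level")


@dataclass(frozen=True)
class NoiseModel:
    """Frame-level detection imperfection."""

    false_negative_rate: float = 0.0
    false_positive_rate: float = 0.0
    confidence_jitter_sd: float = 0.0
    bbox_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("false_negative_rate", "false_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.confidence_jitter_sd < 0 or self.bbox_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")


PATIENT_PROFILE = ParticipantProfile(
    profile_id="patient_default",
    per_step_error_prob=0.5,
    hesitation_log_mean=math.log(6.0),
    hesitation_log_sd=0.4,
    cue_responsiveness={1: 0.85, 2: 0.90, 3: 0.95, 4: 0.98, 5: 1.0},
    base_action_duration_s=8.0,
)

CONTROL_PROFILE = ParticipantProfile(
    profile_id="control_default",
    per_step_error_prob=0.05,
    hesitation_log_mean=math.log(1.2),
    hesitation_log_sd=0.3,
    cue_responsiveness={1: 0.95, 2: 0.97, 3: 0.99, 4: 1.0, 5: 1.0},
    base_action_duration_s=4.0,
)

PERFECT_PROFILE = ParticipantProfile(
    profile_id="perfect",
    per_step_error_prob=0.0,
    hesitation_log_mean=math.log(0.2),
    hesitation_log_sd=0.0,
    cue_responsiveness={1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0},
    base_action_duration_s=2.0,
)

DEFAULT_NOISE = NoiseModel(
    false_negative_rate=0.05,
    false_positive_rate=0.02,
    confidence_jitter_sd=0.05,
    bbox_jitter_sd=0.01,
)

ZERO_NOISE = NoiseModel()

#: Canonical scene layout (normalized bboxes) for the default
#: egg-boiling vocabulary; classes outside it get a deterministic
#: hash-derived slot.  Pot-state classes overlap the cooker so the
#: default module's spatial predicate holds once the pot is placed.
_HOME_BBOXES: dict[str, tuple[float, float, float, float]] = {
    "cooker_off": (0.40, 0.55, 0.28, 0.30),
    "cooker_on": (0.40, 0.55, 0.28, 0.30),
    "cooker_lid_open": (0.70, 0.50, 0.15, 0.12),
    "cooker_lid_closed": (0.42, 0.50, 0.24, 0.10),
    "pot_stored": (0.05, 0.60, 0.15, 0.18),
    "pot_empty": (0.45, 0.48, 0.18, 0.16),
    "pot_with_water": (0.45, 0.48, 0.18, 0.16),
    "pot_with_egg": (0.45, 0.48, 0.18, 0.16),
    "pitcher_stored": (0.82, 0.62, 0.12, 0.22),
    "pitcher_ready": (0.66, 0.46, 0.12, 0.22),
    "egg_raw": (0.22, 0.78, 0.06, 0.08),
    "pot_dropped": (0.30, 0.85, 0.18, 0.12),
    "pitcher_tipped": (0.60, 0.70, 0.20, 0.12),
    "water_spilled": (0.35, 0.75, 0.25, 0.10),
    "egg_dropped": (0.50, 0.85, 0.06, 0.08),
    "lid_misaligned": (0.50, 0.40, 0.20, 0.12),
    "wrong_button": (0.38, 0.68, 0.06, 0.06),
}

_TRUE_CONFIDENCE = 0.9
_FP_CONFIDENCE = 0.6
_HAND_HOME = (0.5, 0.6)


def _home_bbox(cls: str) -> tuple[float, float, float, float]:
    if cls in _HOME_BBOXES:
        return _HOME_BBOXES[cls]
    h = zlib.crc32(cls.encode())
    return (0.05 + (h % 8) * 0.11, 0.05 + ((h // 8) % 8) * 0.11, 0.08, 0.08)


@dataclass(frozen=True)
class Segment:
    """One homogeneous interval of the scripted timeline (seconds)."""

    t0_s: float
    t1_s: float
    classes: frozenset[str]
    step_id: str
    hand_present: bool


@dataclass
class GroundTruth:
    """True timeline behind a simulated stream."""

    segments: list[Segment]
    step_intervals: list[tuple[str, float, float]]  # (step_id, t0_ms, t1_ms)
    state_change_times_ms: dict[str, float]  # step_id -> true transition time
    frame_step_ids: list[str] = field(default_factory=list)
    frame_true_classes: list[frozenset[str]] = field(default_factory=list)


def _initial_scene(module: TaskModule) -> set[str]:
    """Classes visible before any step: those a step requires absent (or
    references spatially) without an earlier step having produced them."""
    added: set[str] = set()
    initial: set[str] = set()
    for step in module.steps:
        cond = step.completion_condition
        for c in cond.required_absent:
            if c not in added:
                initial.add(c)
        for pred in cond.spatial_predicates:
            for c in (pred.subject, pred.object_):
                if c not in added and c not in cond.required_present:
                    initial.add(c)
        added |= cond.required_present
    return initial


def _cue_level_at(step, elapsed_s: float) -> int:
    level = 0
    for lv in sorted(step.cue_schedule):
        if elapsed_s >= step.cue_schedule[lv].timeout_s:
            level = lv
    return level


def _build_timeline(
    module: TaskModule,
    profile: ParticipantProfile,
    assisted: bool,
    rng_participant: np.random.Generator,
    rng_condition: np.random.Generator,
) -> GroundTruth:
    scene = _initial_scene(module)
    segments: list[Segment] = []
    step_intervals: list[tuple[str, float, float]] = []
    transitions: dict[str, float] = {}
    t = 0.0
    for step in module.steps:
        t_start = t
        hesitation = float(
            rng_participant.lognormal(
                profile.hesitation_log_mean, profile.hesitation_log_sd
            )
        )
        err_drawn = bool(rng_participant.random() < profile.per_step_error_prob)
        pace = float(rng_participant.uniform(0.8, 1.2))

        segments.append(
            Segment(t, t + hesitation, frozenset(scene), step.step_id, False)
        )
        t += hesitation

        if err_drawn and step.error_conditions:
            err_classes = step.error_conditions[0].condition.required_present
            err_scene = frozenset(scene | err_classes)
            t_err_start = t
            while True:
                segments.append(
                    Segment(
                        t,
                        t + CORRECTION_CHECK_INTERVAL_S,
                        err_scene,
                        step.step_id,
                        True,
                    )
                )
                t += CORRECTION_CHECK_INTERVAL_S
                if assisted:
                    level = max(1, _cue_level_at(step, t - t_start))
                    levels = sorted(profile.cue_responsiveness)
                    usable = [lv for lv in levels if lv <= level] or levels[:1]
                    p = profile.cue_responsiveness[usable[-1]]
                else:
                    p = profile.unassisted_recovery_prob
                if rng_condition.random() < p:
                    break
                if t - t_err_start >= MAX_ERROR_EPISODE_S:
                    break

        action = profile.base_action_duration_s * pace
        segments.append(Segment(t, t + action, frozenset(scene), step.step_id, True))
        t += action

        cond = step.completion_condition
        scene = (scene | cond.required_present) - cond.required_absent
        transitions[step.step_id] = t * 1000.0
        step_intervals.append((step.step_id, t_start * 1000.0, t * 1000.0))

    last = module.steps[-1].step_id
    segments.append(Segment(t, t + TAIL_S, frozenset(scene), last, False))
    return GroundTruth(
        segments=segments,
        step_intervals=step_intervals,
        state_change_times_ms=transitions,
    )


def _jitter_bbox(
    bbox: tuple[float, float, float, float],
    sd: float,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    x, y, w, h = bbox
    dx, dy = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
    x = min(max(0.0, x + float(dx)), 1.0 - w)
    y = min(max(0.0, y + float(dy)), 1.0 - h)
    return (x, y, w, h)


def simulate_session(
    module: TaskModule,
    profile: ParticipantProfile,
    noise: NoiseModel,
    assisted: bool,
    frame_period_ms: float = DEFAULT_FRAME_PERIOD_MS,
    seed: int = 0,
) -> tuple[list[Frame], GroundTruth]:
    """Generate one session's frame stream plus its ground truth.

    Fully reproducible: identical arguments give byte-identical streams.
    """
    if frame_period_ms <= 0:
        raise ValueError("frame_period_ms must be > 0")
    pkey = zlib.crc32(profile.profile_id.encode()) & 0x7FFFFFFF
    rng_participant = np.random.default_rng([seed, pkey, profile.seed, 7])
    rng_condition = np.random.default_rng(
        [seed, pkey, profile.seed, 11 if assisted else 13]
    )
    truth = _build_timeline(module, profile, assisted, rng_participant, rng_condition)

    vocab = sorted(module.class_vocabulary)
    frames: list[Frame] = []
    seg_idx = 0
    segments = truth.segments
    end_s = segments[-1].t1_s
    n_frames = int(end_s * 1000.0 / frame_period_ms)
    for k in range(n_frames):
        t_ms = k * frame_period_ms
        t_s = t_ms / 1000.0
        while seg_idx + 1 < len(segments) and t_s >= segments[seg_idx].t1_s:
            seg_idx += 1
        seg = segments[seg_idx]
        true_classes = seg.classes

        detections: list[ObjectDetection] = []
        for cls in sorted(true_classes):
            if noise.false_negative_rate > 0 and (
                rng_condition.random() < noise.false_negative_rate
            ):
                continue
            conf = _TRUE_CONFIDENCE
            if noise.confidence_jitter_sd > 0:
                conf += float(rng_condition.normal(0.0, noise.confidence_jitter_sd))
            conf = min(1.0, max(0.05, conf))
            bbox = _jitter_bbox(_home_bbox(cls), noise.bbox_jitter_sd, rng_condition)
            detections.append(ObjectDetection(cls, conf, bbox))
        if noise.false_positive_rate > 0:
            for cls in vocab:
                if cls in true_classes:
                    continue
                if rng_condition.random() < noise.false_positive_rate:
                    conf = _FP_CONFIDENCE
                    if noise.confidence_jitter_sd > 0:
                        conf += float(
                            rng_condition.normal(0.0, noise.confidence_jitter_sd)
                        )
                    conf = min(1.0, max(0.05, conf))
                    bbox = _jitter_bbox(
                        _home_bbox(cls), noise.bbox_jitter_sd, rng_condition
                    )
                    detections.append(ObjectDetection(cls, conf, bbox))

        if seg.hand_present:
            cx, cy = _HAND_HOME
            if noise.bbox_jitter_sd > 0:
                dc = rng_condition.normal(0.0, noise.bbox_jitter_sd, size=2)
                cx, cy = cx + float(dc[0]), cy + float(dc[1])
            centroid = (min(1.0, max(0.0, cx)), min(1.0, max(0.0, cy)))
        else:
            centroid = None

        frames.append(
            Frame(
                timestamp_ms=t_ms,
                detections=detections,
                hand_present=seg.hand_present,
                hand_centroid=centroid,
            )
        )
        truth.frame_step_ids.append(seg.step_id)
        truth.frame_true_classes.append(true_classes)

    return frames, truth


def label_frames(
    ground_truth: GroundTruth, frames: list[Frame]
) -> list[FrameLabelPair]:
    """Pair each frame's predicted class set with its true class set,
    assigned to the step active at its timestamp."""
    if len(frames) != len(ground_truth.frame_true_classes):
        raise ValueError(
            f"{len(frames)} frames but ground truth covers "
            f"{len(ground_truth.frame_true_classes)}"
        )
    pairs = []
    for frame, true_cls, step_id in zip(
        frames, ground_truth.frame_true_classes, ground_truth.frame_step_ids
    ):
        pairs.append(
            FrameLabelPair(
                timestamp_ms=frame.timestamp_ms,
                true_classes=frozenset(true_cls),
                predicted_classes=frozenset(d.class_label for d in frame.detections),
                step_id=step_id,
            )
        )
    return pairs


@dataclass
class CohortDataset:
    """Paired-design session dataset: one unassisted and one assisted
    session per virtual participant."""

    summary: pd.DataFrame
    records: dict[tuple[str, str], SessionRecord]

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def simulate_cohort(
    module: TaskModule,
    n_patients: int,
    n_controls: int,
    patient_profile: ParticipantProfile = PATIENT_PROFILE,
    control_profile: ParticipantProfile = CONTROL_PROFILE,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
    frame_period_ms: float = DEFAULT_FRAME_PERIOD_MS,
    params: EngineParams = EngineParams(),
    p_male: dict[str, float] = {"patient": 0.25, "control": 0.15},
) -> CohortDataset:
    """Simulate, replay, and score a full two-group paired cohort.

    Each participant performs the task once unassisted and once with
    guidance (shared participant-level behavior draws across the pair).
    Returns a session-summary table (one row per session) plus the full
    session records.
    """
    if n_patients < 1 or n_controls < 1:
        raise ValueError("need at least one participant per group")
    rows = []
    records: dict[tuple[str, str], SessionRecord] = {}
    roster = [("patient", patient_profile, i) for i in range(n_patients)] + [
        ("control", control_profile, i) for i in range(n_controls)
    ]
    for group, base_profile, i in roster:
        pid = f"{group}_{i + 1:02d}"
        profile = dataclasses.replace(base_profile, profile_id=pid)
        pkey = zlib.crc32(pid.encode()) & 0x7FFFFFFF
        sex_rng = np.random.default_rng([seed, pkey, 99])
        sex = "male" if sex_rng.random() < p_male[group] else "female"
        for condition in ("unassisted", "assisted"):
            assisted = condition == "assisted"
            frames, _ = simulate_session(
                module, profile, noise, assisted, frame_period_ms, seed
            )
            record = run_session(
                module,
                frames,
                assisted=assisted,
                params=params,
                session_id=f"{pid}_{condition}",
                participant_id=pid,
            )
            completion = score_completion(record, module)
            efpt = score_efpt(record, module)
            records[(pid, condition)] = record
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "sex": sex,
                    "condition": condition,
                    "assisted": assisted,
                    "completion_time_s": record.total_completion_time_s,
                    "completion_score": completion.total,
                    "efpt_score": efpt.total,
                    "n_errors": sum(record.error_count.values()),
                    "steps_completed": sum(
                        t.completed for t in record.step_timings.values()
                    ),
                }
            )
    return CohortDataset(summary=pd.DataFrame(rows), records=records)
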