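"""Detection-frame streams and the rolling-average presence stabilizer.

The guidance engine never sees raw video: it consumes *frames* — a
timestamp, a list of object detections (class label, confidence,
normalized bbox), and a hand-presence flag from the hand-tracking
module.  Raw per-frame detections flicker, so before any state decision
the per-class presence signal is smoothed with a rolling average over a
fixed window of frames (5 by default, matching the deployed system).

Coordinates are normalized to [0, 1] with the origin at the top-left of
the image and y increasing downward.  Streams are serialized as JSON
lines, one frame per line; the writer/reader round-trip is bit-exact.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .config import SpatialPredicate

__all__ = [
    "ObjectDetection",
    "Frame",
    "SmoothedState",
    "StreamError",
    "read_frames",
    "write_frames",
    "frame_to_dict",
    "frame_from_dict",
    "RollingSmoother",
    "smooth",
    "is_present",
    "evaluate_spatial",
    "best_detection",
    "DEFAULT_PRESENCE_THRESHOLD",
]

#: Inclusive presence-score threshold: a class counts as present when its
#: smoothed score is >= this value, so 3 positive binary frames out of a
#: 5-frame window pass.
DEFAULT_PRESENCE_THRESHOLD = 0.5


class StreamError(ValueError):
    """A frame stream violated its contract (ordering or syntax)."""


@dataclass(frozen=True)
class ObjectDetection:
    """One detected object: class label, confidence, normalized bbox."""

    class_label: str
    confidence: float
    bbox: tuple[float, float, float, float]  # (x_min, y_min, width, height)

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        x, y, w, h = self.bbox
        if x < 0 or y < 0 or w < 0 or h < 0 or x + w > 1 + 1e-9 or y + h > 1 + 1e-9:
            raise ValueError(f"bbox {self.bbox} outside the unit square")

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        return (x + w / 2.0, y + h / 2.0)


@dataclass
class Frame:
    timestamp_ms: float
    detections: list[ObjectDetection] = field(default_factory=list)
    hand_present: bool = False
    hand_centroid: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.timestamp_ms < 0:
            raise ValueError("timestamp_ms must be non-negative")
        if self.hand_centroid is not None and not self.hand_present:
            raise ValueError("hand_centroid given but hand_present is False")


@dataclass
class SmoothedState:
    """Per-class rolling-average presence at one timestamp.

    Classes absent from ``presence`` are implicitly 0.
    """

    timestamp_ms: float
    presence: dict[str, float]
    hand_presence_score: float


def frame_to_dict(frame: Frame) -> dict:
    return {
        "timestamp_ms": frame.timestamp_ms,
        "detections": [
            {"label": d.class_label, "confidence": d.confidence, "bbox": list(d.bbox)}
            for d in frame.detections
        ],
        "hand_present": frame.hand_present,
        "hand_centroid": list(frame.hand_centroid) if frame.hand_centroid else None,
    }


def frame_from_dict(data: dict) -> Frame:
    centroid = data.get("hand_centroid")
    return Frame(
        timestamp_ms=data["timestamp_ms"],
        detections=[
            ObjectDetection(d["label"], d["confidence"], tuple(d["bbox"]))
            for d in data.get("detections", [])
        ],
        hand_present=bool(data.get("hand_present", False)),
        hand_centroid=tuple(centroid) if centroid is not None else None,
    )


def read_frames(path: str | Path) -> Iterator[Frame]:
    """Yield frames from a JSON-lines file, enforcing timestamp order.

    Malformed lines raise :class:`StreamError` with the line number;
    a non-monotone timestamp raises at the offending line.  An empty
    file yields nothing.
    """
    prev = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                frame = frame_from_dict(json.loads(line))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise StreamError(f"{path}:{lineno}: malformed frame: {exc}") from exc
            if prev is not None and frame.timestamp_ms <= prev:
                raise StreamError(
                    f"{path}:{lineno}: timestamp {frame.timestamp_ms} not after {prev}"
                )
            prev = frame.timestamp_ms
            yield frame


def write_frames(frames: Iterable[Frame], path: str | Path) -> int:
    """Write frames as JSON lines; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(json.dumps(frame_to_dict(frame)) + "\n")
            n += 1
    return n


def _frame_presence(frame: Frame, binary: bool) -> dict[str, float]:
    """Per-frame presence value per class: max confidence (or 1.0 in
    binary mode) over that class's detections, 0 if absent."""
    values: dict[str, float] = {}
    for det in frame.detections:
        v = 1.0 if binary else det.confidence
        if v > values.get(det.class_label, 0.0):
            values[det.class_label] = v
    return values


class RollingSmoother:
    """Incremental rolling-average stabilizer over detection frames.

    For frame k (1-based) the smoothed presence of class c is the mean
    of the per-frame presence values of c over the last
    ``min(window, k)`` frames — warm-up frames average over what is
    available so the system can react from frame 1.  Hand presence is
    smoothed the same way from the boolean flag.
    """

    def __init__(
        self,
        window: int,
        class_vocabulary: Optional[Iterable[str]] = None,
        binary: bool = False,
    ) -> None:
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self.binary = binary
        self.vocabulary = set(class_vocabulary) if class_vocabulary else None
        self._buffer: deque[dict[str, float]] = deque()
        self._hand: deque[float] = deque()

    def push(self, frame: Frame) -> SmoothedState:
        values = _frame_presence(frame, self.binary)
        if self.vocabulary is not None:
            values = {c: v for c, v in values.items() if c in self.vocabulary}
        if len(self._buffer) == self.window:
            self._buffer.popleft()
            self._hand.popleft()
        self._buffer.append(values)
        self._hand.append(1.0 if frame.hand_present else 0.0)
        # window is small: recompute sums in frame order so results are
        # bit-identical to a brute-force sliding mean, with no drift
        n = len(self._buffer)
        sums: dict[str, float] = {}
        for entry in self._buffer:
            for c, v in entry.items():
                sums[c] = sums.get(c, 0.0) + v
        presence = {c: s / n for c, s in sums.items()}
        hand = sum(self._hand) / n
        return SmoothedState(frame.timestamp_ms, presence, hand)


def smooth(
    frames: Iterable[Frame],
    window: int,
    class_vocabulary: Optional[Iterable[str]] = None,
    binary: bool = False,
) -> Iterator[SmoothedState]:
    """Smooth a frame stream; one :class:`SmoothedState` per input frame.

    Streaming and batch use produce identical output frame-by-frame.
    With ``window=1`` the output equals the per-frame presence exactly.
    """
    smoother = RollingSmoother(window, class_vocabulary, binary)
    for frame in frames:
        yield smoother.push(frame)


def is_present(
    state: SmoothedState, class_label: str, threshold: float = DEFAULT_PRESENCE_THRESHOLD
) -> bool:
    """True iff the smoothed presence of ``class_label`` is >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return state.presence.get(class_label, 0.0) >= threshold


def best_detection(
    frame: Frame, class_label: str
) -> Optional[ObjectDetection]:
    """Highest-confidence detection of a class in a frame.

    Ties broken deterministically by smaller x_min, then smaller y_min.
    """
    candidates = [d for d in frame.detections if d.class_label == class_label]
    if not candidates:
        return None
    return min(candidates, key=lambda d: (-d.confidence, d.bbox[0], d.bbox[1]))


def _iou(a: ObjectDetection, b: ObjectDetection) -> float:
    ax, ay, aw, ah = a.bbox
    bx, by, bw, bh = b.bbox
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def evaluate_spatial(
    relation: str, subject: ObjectDetection, object_: ObjectDetection
) -> bool:
    """Evaluate a spatial relation between two detections.

    contains: subject center inside object bbox (inclusive boundaries);
    overlaps: intersection-over-union strictly positive;
    above: subject center y < object center y (image convention).
    """
    if relation == "contains":
        cx, cy = subject.center
        ox, oy, ow, oh = object_.bbox
        return ox <= cx <= ox + ow and oy <= cy <= oy + oh
    if relation == "overlaps":
        return _iou(subject, object_) > 0.0
    if relation == "above":
        return subject.center[1] < object_.center[1]
    raise ValueError(f"unknown spatial relation {relation!r}")


def spatial_predicate_holds(pred: SpatialPredicate, frame: Frame) -> bool:
    """A predicate holds when both classes are detected in the frame and
    the relation holds between their best detections."""
    subj = best_detection(frame, pred.subject)
    obj = best_detection(frame, pred.object_)
    if subj is None or obj is None:
        return False
    return evaluate_spatial(pred.relation, subj, obj)
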