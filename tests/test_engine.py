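"""Guidance state machine: advancement, errors, cues, timings."""

import numpy as np
import pytest

from reference import naive_run_session, random_module, random_stream
from taskguide.config import CueLevel, StepCondition, TaskModule, TaskStep, ErrorCondition
from taskguide.detection import Frame, ObjectDetection
from taskguide.engine import (
    compute_timings,
    read_session,
    run_session,
    write_session,
)
from taskguide.simulator import PERFECT_PROFILE, ZERO_NOISE, simulate_session


def scripted_module(n_steps, dwell=1, window=1, cue_timeouts=(), time_limit=60.0):
    """A module whose step i completes when class done<i> is visible."""
    steps = []
    for i in range(n_steps):
        steps.append(
            TaskStep(
                step_id=f"step{i}",
                index=i,
                instruction_text=f"do {i}",
                completion_condition=StepCondition(
                    required_present={f"done{i}"}, dwell_frames=dwell
                ),
                error_conditions=[
                    ErrorCondition(
                        condition=StepCondition(
                            required_present={f"err{i}"}, dwell_frames=1
                        ),
                        corrective_instruction=f"undo the mistake in step {i}",
                    )
                ],
                time_limit_s=time_limit,
                cue_schedule={
                    lv + 1: CueLevel(timeout_s=t, text=f"cue {lv + 1}")
                    for lv, t in enumerate(cue_timeouts)
                },
            )
        )
    return TaskModule(
        module_id="scripted", name="scripted", steps=steps, smoothing_window=window
    )


def frames_from_script(class_sets, period_ms=100.0, hand=True):
    frames = []
    for k, classes in enumerate(class_sets):
        frames.append(
            Frame(
                timestamp_ms=k * period_ms,
                detections=[
                    ObjectDetection(c, 0.9, (0.1, 0.1, 0.2, 0.2)) for c in sorted(classes)
                ],
                hand_present=hand if isinstance(hand, bool) else hand(k),
                hand_centroid=(0.5, 0.5)
                if (hand if isinstance(hand, bool) else hand(k))
                else None,
            )
        )
    return frames


def test_perfect_run_completes_all_steps_with_feedback(module):
    """A flawless participant: every step completed, 'great' after each,
    no errors, no cues."""
    frames, _ = simulate_session(module, PERFECT_PROFILE, ZERO_NOISE, assisted=True, seed=5)
    record = run_session(module, frames, assisted=True)
    assert len(record.events_of_kind("step_completed")) == 6
    assert len(record.events_of_kind("positive_feedback")) == 6
    assert record.events_of_kind("error_detected") == []
    assert record.events_of_kind("cue_issued") == []
    assert all(v == 0 for v in record.max_cue_level.values())
    assert record.completed


def test_error_episode_fires_once_then_step_completes():
    module = scripted_module(3)
    script = (
        [set()] * 2
        + [{"done0"}]          # step 0 completes
        + [{"err1"}] * 5       # error state held: fires once, stays latched
        + [set()] * 3          # error clears
        + [{"done1"}]          # step 1 completes
        + [{"done1", "done2"}]  # step 2 completes
    )
    record = run_session(module, frames_from_script(script), assisted=True)
    assert record.error_count == {"step0": 0, "step1": 1, "step2": 0}
    assert len(record.events_of_kind("error_detected")) == 1
    assert len(record.events_of_kind("corrective_shown")) == 1
    assert record.step_timings["step1"].completed
    assert record.completed


def test_error_resets_completion_dwell():
    # completion needs 3 consecutive holds; an error on the third frame
    # resets the count, so completion happens 3 frames after the error clears
    module = scripted_module(1, dwell=3)
    script = [
        {"done0"},
        {"done0"},
        {"done0", "err0"},  # error wins the tie, dwell resets
        {"done0"},
        {"done0"},
        {"done0"},
        {"done0"},
    ]
    record = run_session(module, frames_from_script(script), assisted=True)
    assert record.error_count["step0"] == 1
    done = record.events_of_kind("step_completed")
    assert done and done[0].timestamp_ms == 500.0


def test_stream_exhausted_mid_task_marks_rest_incomplete():
    module = scripted_module(6)
    # steps 0..2 complete back to back, then the stream just ends
    script = [set(), {"done0"}, {"done1"}, {"done2"}, set(), set()]
    record = run_session(module, frames_from_script(script), assisted=True)
    for i in range(3):
        assert record.step_timings[f"step{i}"].completed
    for i in range(3, 6):
        assert not record.step_timings[f"step{i}"].completed
        assert record.step_timings[f"step{i}"].duration_s is None
    assert record.total_completion_time_s is None
    assert record.events[-1].kind == "session_end"
    assert record.events[-1].detail == "stream exhausted"


def test_cue_levels_escalate_in_order_and_level5_force_advances():
    module = scripted_module(1, cue_timeouts=(1, 2, 3, 4, 5))
    script = [set()] * 60  # never completes; 100 ms period -> stalls 5.9 s
    record = run_session(module, frames_from_script(script), assisted=True)
    cues = record.events_of_kind("cue_issued")
    assert [c.cue_level for c in cues] == [1, 2, 3, 4, 5]
    assert all(a.timestamp_ms < b.timestamp_ms for a, b in zip(cues, cues[1:]))
    assert record.max_cue_level["step0"] == 5
    # performed by the assessor: resolved but not completed
    assert not record.step_timings["step0"].completed
    assert record.completed  # session ended with all steps resolved


def test_step_completed_events_in_index_order(module):
    frames, _ = simulate_session(module, PERFECT_PROFILE, ZERO_NOISE, assisted=True, seed=9)
    record = run_session(module, frames, assisted=True)
    order = [e.step_id for e in record.events_of_kind("step_completed")]
    assert order == [s.step_id for s in module.steps]


def test_determinism_byte_identical_logs(module):
    frames, _ = simulate_session(module, PERFECT_PROFILE, ZERO_NOISE, assisted=True, seed=2)
    a = run_session(module, frames, assisted=True)
    b = run_session(module, frames, assisted=True)
    assert a.events == b.events
    assert a.step_timings == b.step_timings


def test_assisted_unassisted_symmetry():
    """The same stream satisfies step conditions at identical times in
    both modes; only feedback/cue events differ."""
    rng = np.random.default_rng(77)
    for _ in range(10):
        module = random_module(rng)
        frames = random_stream(rng)
        a = run_session(module, frames, assisted=True)
        u = run_session(module, frames, assisted=False)
        assert [
            (e.timestamp_ms, e.step_id) for e in a.events_of_kind("step_completed")
        ] == [(e.timestamp_ms, e.step_id) for e in u.events_of_kind("step_completed")]
        assert a.max_cue_level == u.max_cue_level
        assert a.error_count == u.error_count
        for kind in ("corrective_shown", "cue_issued", "positive_feedback"):
            assert u.events_of_kind(kind) == []


def test_unassisted_logs_cue_milestones_silently():
    module = scripted_module(1, cue_timeouts=(1, 2))
    record = run_session(module, frames_from_script([set()] * 30), assisted=False)
    assert record.events_of_kind("cue_issued") == []
    assert record.max_cue_level["step0"] == 2


class TestTimings:
    def test_initiation_and_duration_from_hand_and_completion(self):
        module = scripted_module(1, dwell=1, window=1)
        # instruction at t=0; hand first present at 1500 ms; completion at 9000 ms
        script = [{"done0"} if k == 18 else set() for k in range(19)]
        frames = frames_from_script(script, period_ms=500.0, hand=lambda k: k >= 3)
        record = run_session(module, frames, assisted=True)
        timing = record.step_timings["step0"]
        assert timing.initiation_time_s == pytest.approx(1.5)
        assert timing.duration_s == pytest.approx(9.0)

    def test_hand_present_at_instruction_gives_zero_initiation(self):
        module = scripted_module(1)
        record = run_session(
            module, frames_from_script([set(), {"done0"}]), assisted=True
        )
        assert record.step_timings["step0"].initiation_time_s == 0.0

    def test_no_hand_reports_missing_initiation_not_zero(self):
        module = scripted_module(1)
        record = run_session(
            module, frames_from_script([set(), {"done0"}], hand=False), assisted=True
        )
        assert record.step_timings["step0"].initiation_time_s is None
        df = compute_timings(record)
        assert np.isnan(df.loc[df.step_id == "step0", "initiation_s"]).all()

    def test_back_to_back_step_durations_sum_to_total(self):
        durations = [10, 15, 20, 15, 20, 12]  # seconds; total 92
        module = scripted_module(6)
        cumulative = np.cumsum(durations)
        script = []
        for k in range(int(cumulative[-1] * 2) + 1):  # 500 ms frames
            t = k * 0.5
            script.append({f"done{j}" for j in range(6) if cumulative[j] <= t})
        record = run_session(module, frames_from_script(script, period_ms=500.0))
        assert record.total_completion_time_s == pytest.approx(92.0)
        per_step = [record.step_timings[f"step{i}"].duration_s for i in range(6)]
        assert per_step == pytest.approx(durations)
        df = compute_timings(record)
        assert df.loc[df.step_id == "__total__", "duration_s"].item() == pytest.approx(92.0)

    def test_requires_an_instruction_event(self):
        from taskguide.engine import SessionRecord

        with pytest.raises(ValueError, match="instruction"):
            compute_timings(SessionRecord("s", "p", True, "m"))


def test_session_round_trip(tmp_path, module):
    frames, _ = simulate_session(module, PERFECT_PROFILE, ZERO_NOISE, assisted=True, seed=4)
    record = run_session(module, frames, assisted=True)
    path = tmp_path / "session.jsonl"
    write_session(record, path)
    again = read_session(path)
    assert again.events == record.events
    assert again.step_timings == record.step_timings
    assert again.total_completion_time_s == record.total_completion_time_s


def test_matches_naive_interpreter_on_scripted_error_case():
    """Cross-check against the quadratic-time reference on the worked
    error scenario (the exhaustive random sweep lives in the acceptance
    suite)."""
    module = scripted_module(3, dwell=2, window=3, cue_timeouts=(0.4, 1.0))
    script = (
        [set()] * 3
        + [{"done0"}] * 4
        + [{"err1"}] * 4
        + [set()] * 2
        + [{"done1"}] * 6
        + [{"done2"}] * 8
    )
    frames = frames_from_script(script)
    for assisted in (True, False):
        a = run_session(module, frames, assisted=assisted)
        b = naive_run_session(module, frames, assisted=assisted)
        assert a.events == b.events
        assert a.step_timings == b.step_timings
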