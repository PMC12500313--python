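"""Synthetic participant simulator: reproducibility, behavior contrast,
noise model, cohort assembly."""

import dataclasses
import json

import numpy as np
import pytest

from taskguide.detection import frame_to_dict
from taskguide.engine import run_session
from taskguide.scoring import score_completion, score_efpt
from taskguide.simulator import (
    CONTROL_PROFILE,
    DEFAULT_NOISE,
    PATIENT_PROFILE,
    PERFECT_PROFILE,
    ZERO_NOISE,
    NoiseModel,
    ParticipantProfile,
    label_frames,
    simulate_cohort,
    simulate_session,
)


def stream_bytes(frames):
    return "\n".join(json.dumps(frame_to_dict(f)) for f in frames).encode()


class TestReproducibility:
    def test_identical_seeds_give_byte_identical_streams(self, module):
        a, _ = simulate_session(module, PATIENT_PROFILE, DEFAULT_NOISE, True, seed=31)
        b, _ = simulate_session(module, PATIENT_PROFILE, DEFAULT_NOISE, True, seed=31)
        assert stream_bytes(a) == stream_bytes(b)

    def test_different_seeds_differ(self, module):
        a, _ = simulate_session(module, PATIENT_PROFILE, DEFAULT_NOISE, True, seed=31)
        b, _ = simulate_session(module, PATIENT_PROFILE, DEFAULT_NOISE, True, seed=32)
        assert stream_bytes(a) != stream_bytes(b)

    def test_fixed_seed_gives_identical_cohort(self, module):
        a = simulate_cohort(module, 2, 1, seed=7)
        b = simulate_cohort(module, 2, 1, seed=7)
        assert a.summary.equals(b.summary)

    def test_paired_sessions_share_participant_level_draws(self, module):
        """The same participant hesitates and errs identically in the
        unassisted and assisted conditions (paired design)."""
        noiseless = dataclasses.replace(PATIENT_PROFILE, profile_id="p1")
        _, gt_u = simulate_session(module, noiseless, ZERO_NOISE, False, seed=3)
        _, gt_a = simulate_session(module, noiseless, ZERO_NOISE, True, seed=3)
        # hesitation segments (the first segment of each step) coincide
        for (sid_u, t0_u, _), (sid_a, t0_a, _) in zip(
            gt_u.step_intervals, gt_a.step_intervals
        ):
            assert sid_u == sid_a
        hes_u = [s for s in gt_u.segments if not s.hand_present][:6]
        hes_a = [s for s in gt_a.segments if not s.hand_present][:6]
        assert [s.t1_s - s.t0_s for s in hes_u] == pytest.approx(
            [s.t1_s - s.t0_s for s in hes_a]
        )


class TestPerfectParticipant:
    def test_noiseless_perfect_run_recovers_ceiling_scores(self, module):
        frames, _ = simulate_session(module, PERFECT_PROFILE, ZERO_NOISE, True, seed=1)
        record = run_session(module, frames, assisted=True)
        assert score_completion(record, module).total == 12
        assert score_efpt(record, module).total == 0

    def test_total_time_tracks_scripted_timeline(self, module):
        frames, truth = simulate_session(module, PERFECT_PROFILE, ZERO_NOISE, True, seed=1)
        record = run_session(module, frames, assisted=True)
        scripted_end_s = truth.step_intervals[-1][2] / 1000.0
        # engine completion lags the true transition by smoothing+dwell latency
        latency_s = (module.smoothing_window + 10) * 0.1
        assert record.total_completion_time_s == pytest.approx(
            scripted_end_s, abs=latency_s
        )

    def test_minimal_cohort_all_sessions_perfect(self, module):
        cohort = simulate_cohort(
            module,
            1,
            1,
            patient_profile=PERFECT_PROFILE,
            control_profile=PERFECT_PROFILE,
            noise=ZERO_NOISE,
            seed=5,
        )
        assert len(cohort.summary) == 4
        assert (cohort.summary.completion_score == 12).all()
        assert (cohort.summary.efpt_score == 0).all()


class TestBehaviorContrast:
    def test_impaired_slower_than_healthy_unassisted(self, module):
        pat, con = [], []
        for seed in range(8):
            fp, _ = simulate_session(module, PATIENT_PROFILE, ZERO_NOISE, False, seed=seed)
            fc, _ = simulate_session(module, CONTROL_PROFILE, ZERO_NOISE, False, seed=seed)
            pat.append(run_session(module, fp, False).total_completion_time_s)
            con.append(run_session(module, fc, False).total_completion_time_s)
        assert np.median(pat) > np.median(con)

    def test_guidance_speeds_up_responsive_error_prone_participants(self, module):
        profile = dataclasses.replace(
            PATIENT_PROFILE, per_step_error_prob=0.5, profile_id="responsive"
        )
        assisted, unassisted = [], []
        for seed in range(12):
            fa, _ = simulate_session(module, profile, ZERO_NOISE, True, seed=seed)
            fu, _ = simulate_session(module, profile, ZERO_NOISE, False, seed=seed)
            assisted.append(run_session(module, fa, True).total_completion_time_s)
            unassisted.append(run_session(module, fu, False).total_completion_time_s)
        assert np.median(assisted) < np.median(unassisted)


class TestNoise:
    def test_zero_noise_predictions_equal_truth(self, module):
        frames, truth = simulate_session(module, PERFECT_PROFILE, ZERO_NOISE, True, seed=2)
        for pair in label_frames(truth, frames):
            assert pair.predicted_classes == pair.true_classes

    def test_total_false_negatives_blank_all_predictions(self, module):
        noise = NoiseModel(false_negative_rate=1.0)
        frames, truth = simulate_session(module, PERFECT_PROFILE, noise, True, seed=2)
        for pair in label_frames(truth, frames):
            assert pair.predicted_classes == frozenset()

    def test_false_positive_rate_matches_binomial_expectation(self, module):
        rate = 0.1
        noise = NoiseModel(false_positive_rate=rate)
        frames, truth = simulate_session(
            module, PATIENT_PROFILE, noise, False, seed=8
        )
        pairs = label_frames(truth, frames)
        vocab_size = len(module.class_vocabulary)
        spurious = np.array(
            [len(p.predicted_classes - p.true_classes) for p in pairs]
        )
        expected = np.array([rate * (vocab_size - len(p.true_classes)) for p in pairs])
        # mean spurious labels/frame ~ Binomial expectation, +/- sampling error
        se = float(np.sqrt(expected.mean() / len(pairs))) * 4 + 0.05
        assert abs(spurious.mean() - expected.mean()) < se

    def test_label_frames_length_mismatch_is_contract_error(self, module):
        frames, truth = simulate_session(module, PERFECT_PROFILE, ZERO_NOISE, True, seed=2)
        with pytest.raises(ValueError, match="frames"):
            label_frames(truth, frames[:-5])


class TestCohort:
    def test_study_sized_cohort_has_38_sessions(self, module):
        cohort = simulate_cohort(module, 12, 7, seed=11)
        assert len(cohort.summary) == 38
        assert cohort.summary.groupby("group").participant_id.nunique().to_dict() == {
            "control": 7,
            "patient": 12,
        }
        # paired design: each participant appears in both conditions
        counts = cohort.summary.groupby("participant_id").condition.nunique()
        assert (counts == 2).all()

    def test_summary_serializes_to_csv(self, module, tmp_path):
        cohort = simulate_cohort(module, 1, 1, seed=3)
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        import pandas as pd

        again = pd.read_csv(path)
        assert list(again.columns) == list(cohort.summary.columns)
        assert len(again) == 4

    def test_empty_group_rejected(self, module):
        with pytest.raises(ValueError):
            simulate_cohort(module, 0, 3)


class TestProfileValidation:
    def test_cue_responsiveness_must_be_non_decreasing(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            dataclasses.replace(
                PATIENT_PROFILE,
                cue_responsiveness={1: 0.9, 2: 0.5, 3: 0.9, 4: 0.9, 5: 1.0},
            )

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            dataclasses.replace(PATIENT_PROFILE, per_step_error_prob=1.5)

    def test_error_episodes_terminate(self, module):
        """Even a participant who never responds to cues produces a
        finite stream (episodes are capped)."""
        stubborn = ParticipantProfile(
            profile_id="stubborn",
            per_step_error_prob=1.0,
            hesitation_log_mean=0.0,
            hesitation_log_sd=0.0,
            cue_responsiveness={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0},
            base_action_duration_s=1.0,
            unassisted_recovery_prob=0.0,
        )
        frames, _ = simulate_session(module, stubborn, ZERO_NOISE, False, seed=1)
        assert len(frames) < 50_000
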