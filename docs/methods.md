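# Methods

## The guidance model

The engine models a guided activity of daily living as a linear sequence
of steps, each defined by a *recognition condition* over the state of the
scene as seen by an object detector. Object classes are state-encoded:
the detector is assumed to report object states (`pot_empty`,
`pot_with_water`, `cooker_on`, …) rather than bare identities, so step
progress is a set-membership question plus optional spatial relations
(contains / overlaps / above on normalized bboxes, image convention:
origin top-left, y downward).

Raw detections flicker, so all state decisions are made on a
rolling-average presence score: per class, the mean over the last
`smoothing_window` frames (default 5, matching the deployed system this
engine models) of the per-frame presence value. The per-frame value is
the maximum detection confidence of the class in the frame (0 if absent);
a binary detected/not-detected mode is available via a flag. The choice
of confidence-weighted smoothing is deliberate: it is robust to duplicate
detections and degrades gracefully for low-confidence frames. Warm-up
frames average over what is available so the system reacts from frame 1.
A class counts as present when its smoothed score is at or above the
presence threshold (default 0.5, inclusive, so 3 positive binary frames
in a 5-frame window suffice).

A step completes when its condition holds on `dwell_frames` consecutive
smoothed states (default 5 — one full smoothing window; the dwell is a
debouncer against transient states). Error conditions are checked first
on every state with their own dwell counters; an error fires once per
episode (it latches until the condition breaks), increments the step's
error count, resets the completion dwell, and — in assisted mode — shows
its corrective instruction. An error and a completion on the same state
resolve in favor of the error (conservative guidance). Stalled steps
escalate cues: level k is reached when the step has been active for its
level-k stall timeout (defaults 15/30/45/60/75 s, configurable per step),
mirroring the five-level assistance hierarchy (verbal, gestural, direct
verbal, physical, performed by the assessor). Level 5 marks the step as
performed by the assessor — resolved but *not completed* — and
force-advances; whether a deployed system would force-advance is an open
design choice, made here so that every session terminates and the
assessor takeover is representable in replay.

Unassisted sessions run the *identical* state machine and record cue
milestones silently, emitting no feedback/cue events. This makes the
modified EFPT computable for both study conditions from replay alone and
guarantees the symmetry property the tests assert: the same stream
satisfies step conditions at identical times in both modes.

Timing capture: initiation time is instruction-to-first-hand-present
(missing, never zero, if no hand appears); step duration is
instruction-to-completion; total completion time is first instruction to
session end and is defined only when every step was resolved.

## Scoring instruments

- **Daily Task Completion Test**: per step, 2 points if completed with no
  error events within the step time limit, 1 if completed but with ≥1
  corrective event or over the limit, 0 if not completed or taken over by
  the assessor (cue level 5). "Partially incorrect" is operationalized as
  completed-with-error-or-overtime because those are the signals the
  engine records, and the instrument is defined on task performance
  accuracy and completion time. Per-step time limits (default 60 s) are
  used rather than a whole-task limit; that convention is declared, not
  derived.
- **Modified EFPT**: components are configurable groupings of steps; a
  component scores the maximum cue level reached across its member steps.
  The default module groups pour-water and place-egg into one component,
  yielding 5 components and the instrument's 0–25 range over a 6-step
  task (a 6-component reading would give 0–30, which contradicts the
  instrument's stated range; the grouping is a declared convention).
- **SUS**: the standard 10-item transformation, validated strictly (no
  imputation). Bands: <50 significant usability issues, [50, 68)
  marginal, [68, 80] acceptable, >80 excellent. The boundary at exactly
  80 is read as acceptable; scores strictly above 80 are excellent. Note
  the source literature for such bands sometimes labels ~80.5 "grade A,
  acceptable" — under the numeric bands implemented here it is excellent.

## Synthetic participants

The simulator exists to exercise every other module end-to-end; it
emulates detection-level data, never pixels, and makes no claim to be a
behavioral model of dementia. Per step the scripted participant
hesitates (log-normal delay, hand absent), possibly enters an error state
(Bernoulli), then acts (base action duration × uniform 0.8–1.2 pace),
after which the scene transitions to the step's completion state. While
in an error state the participant recovers per 5 s check interval with
probability equal to their responsiveness to the currently active cue
level (assisted) or a fixed self-recovery probability of 0.3 (unassisted
participants finish, just slower). Episodes are capped at 90 s so
timelines always terminate.

Default profiles (chosen once as plausible for a mildly impaired vs
healthy older adult on a six-step kitchen task, and sized to land in the
magnitude range of the motivating study's group medians — they are
conditions, not estimates):

| parameter | patient | control |
|---|---|---|
| per-step error probability | 0.5 | 0.05 |
| hesitation (log-normal) | ln 6 s ± 0.4 | ln 1.2 s ± 0.3 |
| base action duration | 8 s | 4 s |
| cue responsiveness (levels 1–5) | .85/.90/.95/.98/1.0 | .95/.97/.99/1.0/1.0 |

Detection noise is frame-level: per-true-class false-negative drops, per-
vocabulary-class false-positive insertions (defaults 0.05 / 0.02),
Gaussian jitter on confidences (SD 0.05) and bbox positions (SD 0.01).
True detections carry confidence 0.9, false positives 0.6, so smoothing
suppresses isolated false positives below the presence threshold — the
stabilizer doing its job is itself a tested property.

The simulator samples at 100 ms (a two-minute session ≈ 1200 frames); the
config default `frame_period_ms = 5` reflects the polling interval of the
modeled live system, and the engine treats the period as data, so both
coexist. Randomness is split into a participant-level stream (hesitation,
error draws, pace) keyed by (seed, participant id) and a condition-level
stream (recovery, noise) additionally keyed by the condition, giving the
paired design shared participant-level draws.

What the simulator does **not** emulate: real detector failure modes
(correlated misses, bbox drift under occlusion, class confusion between
visually similar states), real behavioral structure (perseveration,
sequence errors — participants here never attempt steps out of order),
fatigue or learning across sessions. Passing tests therefore validate
the guidance/scoring logic under controlled conditions, not clinical
effectiveness.

## Evaluation and statistics

Detection quality is scored frame-level on class-set membership
(micro-averaged TP/FP/FN per step), matching how the engine consumes
detections; bbox-IoU benchmarking is out of scope. "Cumulative"
precision/recall is the mean ± SD across task steps; SD is population SD
by default (sample SD by flag), and steps with zero denominators are
excluded from the cumulative summary with a warning.

Cohort summaries report median (Q1–Q3, linear-interpolation quantiles).
Between-group tests use Mann-Whitney, within-group paired tests Wilcoxon
signed-rank (scipy's policy: exact for small tie-free samples, normal
approximation otherwise; all-tied pairs reported as not computable rather
than raised), binary covariates Fisher's exact test; all two-sided.
Percent change is 100·(before − after)/before of group medians, reported
to one decimal. No multiplicity correction is applied, matching the
single-comparison-per-outcome design this mirrors.

## Numerical and testing choices

- The smoother recomputes window sums in frame order rather than keeping
  running sums, so output is bit-identical to a brute-force sliding mean
  (windows are ≤ tens of frames; the cost is negligible and equivalence
  tests can assert exact equality).
- Determinism is contractual: engine runs are pure functions of (module,
  stream, parameters); simulator output is a pure function of (module,
  profile, noise, condition, seed). Tests assert byte-identical replays.
- The engine is cross-checked against an independently written
  quadratic-time interpreter that rescans the stream per step, over 200
  random (module, stream) draws of up to 6 steps and 500 frames.
- Ties in best-detection selection break by confidence, then smaller
  x, then smaller y. Spatial predicates are false when either class is
  undetected in the raw frame.
- Test problem sizes (cohorts of 12 + 7, streams of a few hundred to ~1500
  frames, 20-seed grids) are chosen to make the full suite run in well
  under a minute on one core while still exercising every code path.

## Known limitations

- The six default egg-boiling steps and the ~17-class state vocabulary
  are a plausible stand-in consistent with the modeled system's
  description, not a reconstruction of its actual configuration.
- Cue stall timeouts (15…75 s) and the dwell requirement are engineering
  defaults; the modeled system's real values are not public.
- The simulator's assisted-benefit effect is mechanical (cue
  responsiveness > self-recovery probability); it demonstrates the
  pipeline can detect such an effect, not that the effect exists.
- Only linear step sequences are supported; branching or partially
  ordered tasks would need a richer module schema.
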