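# taskguide

A testable engine for vision-based **cognitive prostheses**: systems that
guide a user step by step through an activity of daily living (the shipped
default is a six-step egg-boiling task) using object-detection streams,
and that quantify how much guidance the user needed.

The package is aimed at researchers and engineers in digital health /
cognitive rehabilitation who want to develop and validate the *guidance
logic* of such a system — the part between the detector and the screen —
without a camera, a trained model, or study participants. It provides:

- **config** — a YAML schema for *task modules*: ordered steps, each with a
  recognition condition over state-encoded object classes (e.g.
  `pot_empty` → `pot_with_water`), error conditions with corrective
  instructions, per-step time limits, and a five-level cue-escalation
  schedule.
- **detection** — frame data model (timestamp, detections, hand presence),
  JSON-lines replay I/O, and the rolling-average presence stabilizer: for
  class $c$ at frame $k$, $\mathrm{presence}_k(c) = \frac{1}{\min(W,k)}
  \sum_{j=k-W+1}^{k} p_j(c)$ with window $W=5$ by default and $p_j(c)$ the
  best detection confidence of $c$ in frame $j$.
- **engine** — the guidance state machine: a step completes when its
  condition holds on `dwell_frames` consecutive smoothed states; errors
  fire corrective instructions and reset the dwell; stalls escalate cues
  level 1→5 (verbal, gestural, direct verbal, physical, performed by the
  assessor); all events and timings (initiation time, step duration, total
  completion time) are logged deterministically.
- **scoring** — the three instruments:
  *Daily Task Completion Test*: per step 2 / 1 / 0 points (fully correct /
  partially incorrect / incorrect), maximum 12 for six steps;
  *modified EFPT* (Executive Function Performance Test, simple-cooking
  adaptation): per component the worst cue level reached, 0–25 total,
  higher = more executive dysfunction;
  *SUS*: $2.5\left[\sum_{\text{odd}}(s_i-1)+\sum_{\text{even}}(5-s_i)\right]$,
  banded `<50 / [50,68) / [68,80] / >80`.
- **simulator** — synthetic participants (log-normal hesitation, Bernoulli
  per-step errors, cue responsiveness) plus frame-level detection noise, and
  paired assisted/unassisted cohort generation.
- **evaluation** — frame-level detection precision/recall/F1 per step,
  per-class confusion counts, and the cumulative (mean ± SD across steps)
  summary.
- **report** — median (IQR) descriptives, Mann-Whitney, Wilcoxon
  signed-rank, Fisher exact, and percent-change-of-medians summaries.

## Worked example

Simulate one guided session of an error-prone participant, replay it
through the engine, and score it:

```python
import taskguide as tg
from taskguide.simulator import PATIENT_PROFILE, DEFAULT_NOISE, simulate_session

module = tg.default_module()
frames, truth = simulate_session(module, PATIENT_PROFILE, DEFAULT_NOISE,
                                 assisted=True, seed=7)
record = tg.run_session(module, frames, assisted=True)
print(tg.compute_timings(record).to_string(index=False))
print("completion:", tg.score_completion(record, module).total)
print("efpt:", tg.score_efpt(record, module).total)
```

prints

```
      step_id  completed  initiation_s  duration_s  errors  max_cue_level
    place_pot       True           6.1        14.3       0              0
fetch_pitcher       True           3.1        16.6       1              1
   pour_water       True           2.9        16.1       2              1
    place_egg       True           9.1        21.3       1              1
    close_lid       True           7.7        17.2       0              1
 press_switch       True           6.1        21.3       1              1
    __total__       True           NaN       106.8       5              1
completion: 8
efpt: 4
```

This participant finished all six steps in 106.8 s but needed five
corrective interventions and a level-1 (verbal) cue on five steps: four
steps therefore earn partial credit (completion 8/12) and four of the five
EFPT components score 1 (EFPT 4/25 — lower is better). A flawless run
scores 12/12 and 0/25. SUS responses are scored separately, e.g.
`tg.score_sus([4,2,4,2,4,2,4,2,4,2])` → 75.0, band `acceptable`.

The same pipeline is available from a shell:

```sh
taskguide simulate --patients 12 --controls 7 --seed 42 --out sim/
taskguide report sim/cohort.csv --out report/
taskguide validate src/taskguide/data/egg_boiling.yaml
```

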