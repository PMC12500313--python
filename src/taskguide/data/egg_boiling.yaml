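# Default six-step egg-boiling task module.
#
# Object classes are state-encoded: the detector reports the *state* of each
# daily-task object (e.g. pot_empty vs pot_with_water), so step completion is
# decided by which state classes are visible, optionally with a spatial
# relation. Class labels are lowercase snake-case. Durations in seconds.
# Cue schedules are omitted and take the standard five-level ladder
# (15/30/45/60/75 s; verbal -> gestural -> direct verbal -> physical ->
# task performed by the assessor).
module_id: egg_boiling
name: Egg boiling (simple cooking task)
frame_period_ms: 5
smoothing_window: 5
steps:
  - step_id: place_pot
    index: 0
    instruction_text: Place the pot on the electric cooker.
    time_limit_s: 60
    completion_condition:
      required_present: [pot_empty]
      required_absent: [pot_stored]
      spatial_predicates:
        - {relation: overlaps, subject: pot_empty, object: cooker_off}
      dwell_frames: 5
    error_conditions:
      - condition:
          required_present: [pot_dropped]
          dwell_frames: 5
        corrective_instruction: The pot is not on the cooker. Pick it up and place it on the cooker.
  - step_id: fetch_pitcher
    index: 1
    instruction_text: Bring the water pitcher next to the pot.
    time_limit_s: 60
    completion_condition:
      required_present: [pitcher_ready]
      required_absent: [pitcher_stored]
      dwell_frames: 5
    error_conditions:
      - condition:
          required_present: [pitcher_tipped]
          dwell_frames: 5
        corrective_instruction: The pitcher tipped over. Stand it upright next to the pot.
  - step_id: pour_water
    index: 2
    instruction_text: Pour water from the pitcher into the pot.
    time_limit_s: 60
    completion_condition:
      required_present: [pot_with_water]
      required_absent: [pot_empty]
      dwell_frames: 5
    error_conditions:
      - condition:
          required_present: [water_spilled]
          dwell_frames: 5
        corrective_instruction: Water spilled outside the pot. Pour slowly into the pot.
  - step_id: place_egg
    index: 3
    instruction_text: Place the egg into the pot.
    time_limit_s: 60
    completion_condition:
      required_present: [pot_with_egg]
      required_absent: [pot_with_water, egg_raw]
      dwell_frames: 5
    error_conditions:
      - condition:
          required_present: [egg_dropped]
          dwell_frames: 5
        corrective_instruction: The egg missed the pot. Pick it up and place it in the pot.
  - step_id: close_lid
    index: 4
    instruction_text: Close the cooker lid.
    time_limit_s: 60
    completion_condition:
      required_present: [cooker_lid_closed]
      required_absent: [cooker_lid_open]
      dwell_frames: 5
    error_conditions:
      - condition:
          required_present: [lid_misaligned]
          dwell_frames: 5
        corrective_instruction: The lid is not seated. Align the lid and close it fully.
  - step_id: press_switch
    index: 5
    instruction_text: Press the cook switch to start cooking.
    time_limit_s: 60
    completion_condition:
      required_present: [cooker_on]
      required_absent: [cooker_off]
      dwell_frames: 5
    error_conditions:
      - condition:
          required_present: [wrong_button]
          dwell_frames: 5
        corrective_instruction: That is not the cook switch. Press the cook switch.
efpt_components:
  - component_id: setup_pot
    member_step_ids: [place_pot]
  - component_id: fetch_water
    member_step_ids: [fetch_pitcher]
  - component_id: fill_and_load
    member_step_ids: [pour_water, place_egg]
  - component_id: close_lid
    member_step_ids: [close_lid]
  - component_id: start_cooking
    member_step_ids: [press_switch]
completion_rules:
  error_downgrades: true
  overtime_downgrades: true
  assessor_cue_level: 5
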