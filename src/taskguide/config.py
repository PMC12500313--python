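"""Task-module configuration: schema, YAML I/O, and validation.

A *task module* is a declarative description of one guided
activity-of-daily-living task: an ordered list of steps, each with a
recognition condition that the guidance engine checks against smoothed
object-detection states, per-step error conditions with corrective
instructions, a five-level cue-escalation schedule, and the groupings
used by the modified Executive Function Performance Test (EFPT).

Task modules are stored one per file as plain YAML mappings.  All
durations are seconds; all class labels are lowercase snake-case strings.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_serializer,
    model_validator,
)

__all__ = [
    "SpatialPredicate",
    "StepCondition",
    "ErrorCondition",
    "CueLevel",
    "TaskStep",
    "EFPTComponent",
    "CompletionRuleSet",
    "TaskModule",
    "TaskModuleError",
    "TaskModuleFormatError",
    "TaskModuleValidationError",
    "load_task_module",
    "write_task_module",
    "validate_task_module",
    "default_module",
    "CUE_LEVEL_NAMES",
    "DEFAULT_MODULE_FILENAME",
]

#: Names of the five assistance levels of the modified EFPT cue hierarchy.
CUE_LEVEL_NAMES: dict[int, str] = {
    1: "verbal assistance",
    2: "gestural assistance",
    3: "direct verbal assistance",
    4: "physical assistance",
    5: "task performed by the assessor",
}

DEFAULT_MODULE_FILENAME = "egg_boiling.yaml"


class TaskModuleError(Exception):
    """Base class for task-module configuration errors."""


class TaskModuleFormatError(TaskModuleError):
    """The YAML document could not be parsed or has the wrong shape."""


class TaskModuleValidationError(TaskModuleError):
    """The document parsed but violates a schema invariant."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SpatialPredicate(_Model):
    """A binary geometric relation between two detected object classes.

    ``contains``: subject bbox center lies inside the object bbox.
    ``overlaps``: the two bboxes have strictly positive intersection.
    ``above``: subject bbox center is above (smaller y than) the object
    bbox center, in image coordinates (y grows downward).
    """

    relation: Literal["contains", "overlaps", "above"]
    subject: str
    object_: str = Field(alias="object")

    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class StepCondition(_Model):
    """A recognition condition over smoothed detection state.

    The condition holds on a smoothed state when every class in
    ``required_present`` has presence score at or above the engine
    threshold, every class in ``required_absent`` is below it, and every
    spatial predicate holds between the best current detections of its
    classes.  The engine requires the condition to hold on
    ``dwell_frames`` consecutive smoothed states before acting on it.
    """

    required_present: set[str] = Field(default_factory=set)
    required_absent: set[str] = Field(default_factory=set)
    spatial_predicates: list[SpatialPredicate] = Field(default_factory=list)
    dwell_frames: int = Field(default=5, ge=1)

    @field_serializer("required_present", "required_absent")
    def _sorted(self, value: set[str]) -> list[str]:
        return sorted(value)

    @model_validator(mode="after")
    def _disjoint(self) -> "StepCondition":
        clash = self.required_present & self.required_absent
        if clash:
            raise ValueError(
                f"classes {sorted(clash)} are both required present and absent"
            )
        return self


class ErrorCondition(_Model):
    """An error state plus the corrective instruction shown when it fires."""

    condition: StepCondition
    corrective_instruction: str


class CueLevel(_Model):
    """One rung of the cue-escalation ladder for a step."""

    timeout_s: float = Field(gt=0)
    text: str


def default_cue_schedule() -> dict[int, CueLevel]:
    """Five escalating cues at 15 s intervals, named after the EFPT levels."""
    return {
        level: CueLevel(timeout_s=15.0 * level, text=CUE_LEVEL_NAMES[level])
        for level in range(1, 6)
    }


class TaskStep(_Model):
    step_id: str
    index: int = Field(ge=0)
    instruction_text: str
    completion_condition: StepCondition
    error_conditions: list[ErrorCondition] = Field(default_factory=list)
    time_limit_s: float = Field(default=60.0, gt=0)
    cue_schedule: dict[int, CueLevel] = Field(default_factory=default_cue_schedule)


class EFPTComponent(_Model):
    """A scored EFPT component: one or more task steps graded together."""

    component_id: str
    member_step_ids: list[str] = Field(min_length=1)


class CompletionRuleSet(_Model):
    """Per-step credit rules for the Daily Task Completion Test.

    A step earns 2 points when completed with no error events inside its
    time limit, 1 point when completed but with at least one corrective
    event or over the limit, and 0 when not completed or when assistance
    reached ``assessor_cue_level``.  The three outcomes partition every
    possible step result.
    """

    error_downgrades: bool = True
    overtime_downgrades: bool = True
    assessor_cue_level: int = Field(default=5, ge=1, le=5)


class TaskModule(_Model):
    module_id: str
    name: str
    steps: list[TaskStep] = Field(min_length=1)
    frame_period_ms: float = Field(default=5.0, gt=0)
    smoothing_window: int = Field(default=5, ge=1)
    efpt_components: list[EFPTComponent] = Field(default_factory=list)
    completion_rules: CompletionRuleSet = Field(default_factory=CompletionRuleSet)

    def step(self, step_id: str) -> TaskStep:
        for s in self.steps:
            if s.step_id == step_id:
                return s
        raise KeyError(step_id)

    @property
    def class_vocabulary(self) -> set[str]:
        """All object classes referenced by any condition in the module."""
        vocab: set[str] = set()
        for s in self.steps:
            conds = [s.completion_condition] + [e.condition for e in s.error_conditions]
            for c in conds:
                vocab |= c.required_present | c.required_absent
                for p in c.spatial_predicates:
                    vocab |= {p.subject, p.object_}
        return vocab

    @property
    def max_completion_score(self) -> int:
        """Ceiling of the Daily Task Completion Test: 2 points per step."""
        return 2 * len(self.steps)

    @property
    def max_efpt_score(self) -> int:
        """Ceiling of the modified EFPT: 5 points per component."""
        return 5 * len(self.efpt_components)


def validate_task_module(module: TaskModule) -> list[str]:
    """Check cross-object invariants; return a list of violations.

    Pure function: the same module always yields the same findings, and
    an empty list means the module is valid.  Field-level constraints
    (ranges, types) are enforced at construction time by the schema;
    this covers the relational rules the schema cannot express.
    """
    violations: list[str] = []

    step_ids = [s.step_id for s in module.steps]
    if len(set(step_ids)) != len(step_ids):
        dupes = sorted({i for i in step_ids if step_ids.count(i) > 1})
        violations.append(f"steps.step_id: duplicate step ids {dupes}")

    indices = sorted(s.index for s in module.steps)
    if indices != list(range(len(module.steps))):
        violations.append(
            f"steps.index: indices {indices} are not contiguous from 0"
        )

    for s in module.steps:
        levels = sorted(s.cue_schedule)
        if levels != list(range(1, len(levels) + 1)):
            violations.append(
                f"steps[{s.step_id}].cue_schedule: levels {levels} are not a "
                "prefix of 1..5"
            )
        elif levels and max(levels) > 5:
            violations.append(
                f"steps[{s.step_id}].cue_schedule: level above 5"
            )
        timeouts = [s.cue_schedule[lv].timeout_s for lv in sorted(s.cue_schedule)]
        if any(b <= a for a, b in zip(timeouts, timeouts[1:])):
            violations.append(
                f"steps[{s.step_id}].cue_schedule: stall timeouts {timeouts} "
                "are not strictly increasing"
            )

    known = set(step_ids)
    seen: dict[str, str] = {}
    comp_ids = [c.component_id for c in module.efpt_components]
    if len(set(comp_ids)) != len(comp_ids):
        violations.append("efpt_components.component_id: duplicate component ids")
    for comp in module.efpt_components:
        for sid in comp.member_step_ids:
            if sid not in known:
                violations.append(
                    f"efpt_components[{comp.component_id}].member_step_ids: "
                    f"unknown step id {sid!r}"
                )
            elif sid in seen:
                violations.append(
                    f"efpt_components[{comp.component_id}].member_step_ids: "
                    f"step {sid!r} already in component {seen[sid]!r} "
                    "(components must be disjoint)"
                )
            else:
                seen[sid] = comp.component_id

    return violations


def _module_from_mapping(data: object) -> TaskModule:
    if not isinstance(data, dict):
        raise TaskModuleFormatError(
            f"top-level YAML document must be a mapping, got {type(data).__name__}"
        )
    try:
        module = TaskModule.model_validate(data)
    except ValidationError as exc:
        msgs = [
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        ]
        raise TaskModuleValidationError(msgs) from exc
    violations = validate_task_module(module)
    if violations:
        raise TaskModuleValidationError(violations)
    return module


def load_task_module(path: str | Path) -> TaskModule:
    """Load and validate a task module from a YAML file.

    Raises :class:`TaskModuleFormatError` (with line information where
    YAML provides it) on malformed documents and
    :class:`TaskModuleValidationError` naming the offending field on
    invariant violations.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise TaskModuleFormatError(f"invalid YAML in {path}{where}: {exc}") from exc
    return _module_from_mapping(data)


def module_to_mapping(module: TaskModule) -> dict:
    """Serialize a module to plain YAML-ready primitives (sets sorted)."""
    return module.model_dump(mode="json", by_alias=True)


def write_task_module(module: TaskModule, path: str | Path) -> None:
    """Write a module as one plain YAML document; round-trips with load."""
    with open(path, "w") as fh:
        yaml.safe_dump(module_to_mapping(module), fh, sort_keys=False)


def default_module() -> TaskModule:
    """The shipped six-step egg-boiling module (five EFPT components)."""
    ref = resources.files("taskguide") / "data" / DEFAULT_MODULE_FILENAME
    data = yaml.safe_load(ref.read_text())
    return _module_from_mapping(data)
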