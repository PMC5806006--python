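"""Domain types, validation, and CSV step-log I/O.

The unit of observation is one participant-day: the goal the app assigned,
the step total the phone recorded (missing whenever the app was off), and
the arm the participant belongs to.  A participant's ordered day records
form a :class:`ParticipantHistory`; histories plus a :class:`StudyConfig`
form a :class:`TrialDataset`, the object every downstream module consumes.

Missing step counts are encoded as absent values (``None`` in records,
blank cells in CSV), never zero: a recorded 0 is a legitimate observation,
while an app-off day carries no information.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

__all__ = [
    "Group",
    "DailyRecord",
    "ParticipantHistory",
    "StudyConfig",
    "TrialDataset",
    "Violation",
    "SchemaError",
    "ValidationError",
    "InsufficientDataError",
    "read_step_log",
    "write_step_log",
    "validate_dataset",
]

CSV_COLUMNS = ["participant_id", "study_day", "group", "goal", "steps", "app_active"]


class SchemaError(ValueError):
    """The file does not match the documented step-log CSV schema."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


class InsufficientDataError(ValueError):
    """Not enough observed days to carry out the requested computation."""


class Group(str, enum.Enum):
    CONTROL = "control"
    INTERVENTION = "intervention"
    UNASSIGNED = "unassigned"

    def __str__(self) -> str:  # so f-strings and CSV cells print the bare value
        return self.value


@dataclass(frozen=True)
class DailyRecord:
    """One participant-day: assigned goal, observed steps, app activity.

    ``steps`` is ``None`` when no step total was recorded for the day.
    Hard impossibilities (nonpositive goal, negative steps, day < 1) raise
    at construction; cross-field and cross-record rules are checked by
    :func:`validate_dataset` so that invalid datasets can be represented
    and reported on.
    """

    participant_id: str
    study_day: int
    goal: int
    steps: Optional[int]
    app_active: bool
    group: Group = Group.UNASSIGNED

    def __post_init__(self) -> None:
        if self.study_day < 1:
            raise ValidationError(f"study_day must be >= 1, got {self.study_day}")
        if self.goal <= 0:
            raise ValidationError(f"goal must be positive, got {self.goal}")
        if self.steps is not None and self.steps < 0:
            raise ValidationError(f"steps must be non-negative, got {self.steps}")

    @property
    def observed(self) -> bool:
        return self.steps is not None


@dataclass
class ParticipantHistory:
    """Ordered daily records for one participant; the unit models fit on."""

    participant_id: str
    records: list[DailyRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def days(self) -> list[int]:
        return [r.study_day for r in self.records]

    @property
    def group(self) -> Group:
        """Arm of the participant: the group recorded from day 8 onward."""
        for r in self.records:
            if r.group is not Group.UNASSIGNED:
                return r.group
        return Group.UNASSIGNED

    def observed_records(self) -> list[DailyRecord]:
        return [r for r in self.records if r.steps is not None]

    def n_observed(self) -> int:
        return sum(1 for r in self.records if r.steps is not None)

    def last_day(self) -> int:
        return self.records[-1].study_day if self.records else 0

    def window(self, last_day: int, width: int) -> list[DailyRecord]:
        """Records with study_day in (last_day - width, last_day]."""
        lo = last_day - width
        return [r for r in self.records if lo < r.study_day <= last_day]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in self.records],
                "study_day": [r.study_day for r in self.records],
                "group": [r.group.value for r in self.records],
                "goal": [r.goal for r in self.records],
                "steps": [r.steps for r in self.records],
                "app_active": [r.app_active for r in self.records],
            }
        )


@dataclass
class StudyConfig:
    """Trial design parameters.

    Defaults mirror a 10-week design with a 1-week run-in, constant
    10,000-step control goals, goals delivered on a 500-step grid, and
    1:1 simple randomization.
    """

    run_in_days: int = 7
    total_weeks: int = 10
    control_goal: int = 10_000
    goal_grid_step: int = 500
    goal_min: int = 2_000
    goal_max: int = 20_000
    allocation_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.goal_min > self.goal_max:
            raise ValueError("goal_min must be <= goal_max")
        if not 0.0 < self.allocation_prob < 1.0:
            raise ValueError("allocation_prob must be in (0, 1)")
        if self.run_in_days > self.total_weeks * 7:
            raise ValueError("run-in cannot exceed the study span")

    @property
    def total_days(self) -> int:
        return self.total_weeks * 7

    def goal_grid(self) -> list[int]:
        return list(range(self.goal_min, self.goal_max + 1, self.goal_grid_step))

    def week_of_day(self, day: int) -> int:
        """1-based study week: week k covers days 7(k-1)+1 .. 7k."""
        return (day - 1) // 7 + 1

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrialDataset:
    """All participants' histories plus the study configuration."""

    histories: list[ParticipantHistory]
    config: StudyConfig = field(default_factory=StudyConfig)

    @property
    def participant_ids(self) -> list[str]:
        return [h.participant_id for h in self.histories]

    def __len__(self) -> int:
        return len(self.histories)

    def get(self, participant_id: str) -> ParticipantHistory:
        for h in self.histories:
            if h.participant_id == participant_id:
                return h
        raise KeyError(participant_id)

    def n_observed(self) -> int:
        return sum(h.n_observed() for h in self.histories)

    def arm(self, group: Group) -> list[ParticipantHistory]:
        return [h for h in self.histories if h.group is group]

    def to_frame(self) -> pd.DataFrame:
        if not self.histories:
            return pd.DataFrame(columns=CSV_COLUMNS)
        return pd.concat([h.to_frame() for h in self.histories], ignore_index=True)


@dataclass(frozen=True)
class Violation:
    """One invariant violation: who, when, which rule."""

    participant_id: str
    study_day: Optional[int]
    rule: str
    message: str

    def __str__(self) -> str:
        day = f" day {self.study_day}" if self.study_day is not None else ""
        return f"[{self.participant_id}{day}] {self.rule}: {self.message}"


def validate_dataset(dataset: TrialDataset) -> list[Violation]:
    """Check every structural invariant; report, never raise.

    Returns an empty list iff the dataset is valid.  Each violation names
    the participant, the study day where applicable, and the rule broken.
    """
    out: list[Violation] = []
    seen_ids: set[str] = set()
    for hist in dataset.histories:
        pid = hist.participant_id
        if pid in seen_ids:
            out.append(Violation(pid, None, "unique participant ids", "duplicate participant id"))
        seen_ids.add(pid)

        prev_day = 0
        post_group: Optional[Group] = None
        for rec in hist.records:
            if rec.participant_id != pid:
                out.append(
                    Violation(pid, rec.study_day, "consistent participant id",
                              f"record labelled {rec.participant_id!r}")
                )
            if rec.study_day <= prev_day:
                rule = "no duplicate days" if rec.study_day == prev_day else "study_day strictly increasing"
                out.append(Violation(pid, rec.study_day, rule,
                                     f"day {rec.study_day} after day {prev_day}"))
            prev_day = max(prev_day, rec.study_day)

            if rec.steps is not None and not rec.app_active:
                out.append(Violation(pid, rec.study_day, "steps missing when app inactive",
                                     "steps recorded on an app_active=false day"))

            if rec.study_day >= 8:
                if rec.group is Group.UNASSIGNED:
                    out.append(Violation(pid, rec.study_day, "group assigned from day 8",
                                         "unassigned group after randomization"))
                elif post_group is None:
                    post_group = rec.group
                elif rec.group is not post_group:
                    out.append(Violation(pid, rec.study_day, "group constant from day 8",
                                         f"group switches {post_group.value} -> {rec.group.value}"))

        have = set(hist.days)
        missing_runin = [d for d in range(1, dataset.config.run_in_days + 1) if d not in have]
        if missing_runin:
            out.append(Violation(pid, None, "run-in days present",
                                 f"missing schedule rows for run-in days {missing_runin}"))
    return out


def _parse_bool(x, where: str) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise SchemaError(f"cannot parse boolean {x!r} in {where}")


def read_step_log(path, config: Optional[StudyConfig] = None) -> TrialDataset:
    """Read a step-log CSV into a validated :class:`TrialDataset`.

    Schema: header ``participant_id,study_day,group,goal,steps,app_active``;
    blank ``steps`` means missing; booleans are ``true``/``false``.  Rows are
    sorted per participant by study day.  Any invariant violation (duplicate
    participant-days, negative steps, nonpositive goals, steps present on
    app-off days, ...) raises :class:`ValidationError`.
    """
    config = config or StudyConfig()
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty step log: {path}") from exc
    if list(df.columns) != CSV_COLUMNS:
        raise SchemaError(
            f"step log header must be {','.join(CSV_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    df = df.sort_values(["participant_id", "study_day"], kind="mergesort")

    histories: list[ParticipantHistory] = []
    for pid, sub in df.groupby("participant_id", sort=True):
        records = []
        for row in sub.itertuples(index=False):
            steps = None if pd.isna(row.steps) else int(row.steps)
            try:
                group = Group(str(row.group).strip().lower())
            except ValueError as exc:
                raise SchemaError(f"unknown group {row.group!r} for {pid}") from exc
            records.append(
                DailyRecord(
                    participant_id=str(pid),
                    study_day=int(row.study_day),
                    goal=int(row.goal),
                    steps=steps,
                    app_active=_parse_bool(row.app_active, f"{pid} day {row.study_day}"),
                    group=group,
                )
            )
        histories.append(ParticipantHistory(participant_id=str(pid), records=records))

    dataset = TrialDataset(histories=histories, config=config)
    violations = validate_dataset(dataset)
    if violations:
        listing = "; ".join(str(v) for v in violations[:5])
        raise ValidationError(f"{len(violations)} invariant violation(s): {listing}")
    return dataset


def write_step_log(dataset: TrialDataset, path) -> None:
    """Write the dataset as a step-log CSV (deterministic formatting)."""
    lines = [",".join(CSV_COLUMNS)]
    for hist in dataset.histories:
        for r in hist.records:
            steps = "" if r.steps is None else str(r.steps)
            active = "true" if r.app_active else "false"
            lines.append(
                f"{r.participant_id},{r.study_day},{r.group.value},{r.goal},{steps},{active}"
            )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
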