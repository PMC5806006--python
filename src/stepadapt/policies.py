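"""Non-learning goal policies and the goal-attainment predicate.

Three fixed rules appear in adaptive-goal trials of this design:

* the run-in ramp — days 1..7 get 3000, 3500, ..., 6000 steps, identical
  in both arms, establishing a reference activity level;
* the active-control rule — a constant goal (10,000 steps/day) from day 8;
* the trailing-percentile rule used by earlier adaptive-goal trials —
  tomorrow's goal is the 60th percentile of the steps taken in the past
  10 days (nearest-rank), snapped to the goal grid.

A day's goal counts as attained when the step total meets or exceeds it;
missing steps propagate to missing attainment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import InsufficientDataError, ParticipantHistory, StudyConfig

__all__ = [
    "RUN_IN_GOALS",
    "GoalPolicy",
    "run_in_goal",
    "control_goal",
    "percentile_goal",
    "goal_attained",
    "nearest_rank_percentile",
    "snap_to_grid",
]

#: Fixed ramp of run-in goals for study days 1..7.
RUN_IN_GOALS = (3000, 3500, 4000, 4500, 5000, 5500, 6000)

POLICY_NAMES = ("run_in", "control", "percentile", "adaptive")


@dataclass(frozen=True)
class GoalPolicy:
    """Named goal policy plus its parameters (used by the simulator/CLI)."""

    name: str
    percentile_p: float = 60.0
    window: int = 10

    def __post_init__(self) -> None:
        if self.name not in POLICY_NAMES:
            raise ValueError(f"unknown policy {self.name!r}; expected one of {POLICY_NAMES}")
        if not 0.0 < self.percentile_p < 100.0:
            raise ValueError("percentile p must lie in (0, 100)")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def run_in_goal(day: int) -> int:
    """Ramp goal for run-in day 1..7: 3000 + 500*(day-1)."""
    if not 1 <= day <= 7:
        raise ValueError(f"run-in covers days 1..7, got day {day}")
    return RUN_IN_GOALS[day - 1]


def control_goal(day: int, config: Optional[StudyConfig] = None) -> int:
    """Control-arm goal: run-in ramp through day 7, constant thereafter."""
    if day < 1:
        raise ValueError(f"study day must be >= 1, got {day}")
    if day <= 7:
        return run_in_goal(day)
    return (config or StudyConfig()).control_goal


def nearest_rank_percentile(values: Sequence[float], p: float) -> float:
    """The ceil(p/100 * n)-th order statistic of ``values``."""
    if not values:
        raise InsufficientDataError("percentile of an empty sample")
    if not 0.0 < p <= 100.0:
        raise ValueError("p must lie in (0, 100]")
    ordered = sorted(values)
    rank = math.ceil(p / 100.0 * len(ordered))
    return ordered[max(rank, 1) - 1]


def snap_to_grid(x: float, config: StudyConfig) -> int:
    """Round to the nearest goal-grid multiple, clipped to [goal_min, goal_max]."""
    step = config.goal_grid_step
    g = int(math.floor(x / step + 0.5)) * step  # round half up, deterministically
    return min(max(g, config.goal_min), config.goal_max)


def percentile_goal(
    history: ParticipantHistory,
    p: float = 60.0,
    window: int = 10,
    config: Optional[StudyConfig] = None,
    as_of_day: Optional[int] = None,
) -> int:
    """Next-day goal: the p-th percentile of observed steps in the trailing window.

    The window spans the last ``window`` study days up to ``as_of_day``
    (default: the last day in the history).  Days with missing steps are
    skipped; if fewer than ``window`` observed values remain the percentile
    is taken over those available (at least one is required).  The result is
    snapped to the goal grid.
    """
    config = config or StudyConfig()
    last = as_of_day if as_of_day is not None else history.last_day()
    obs = [r.steps for r in history.window(last, window) if r.steps is not None]
    if not obs:
        raise InsufficientDataError(
            f"no observed steps in the {window}-day window ending day {last}"
        )
    return snap_to_grid(nearest_rank_percentile(obs, p), config)


def goal_attained(steps: Optional[int], goal: int) -> Optional[bool]:
    """True iff the day's steps met or exceeded the goal; missing propagates."""
    if goal <= 0:
        raise ValueError("goal must be positive")
    if steps is None:
        return None
    return steps >= goal
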