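from __future__ import annotations

import numpy as np
import pytest

from stepadapt.core import DailyRecord, Group, ParticipantHistory, StudyConfig, TrialDataset
from stepadapt.policies import run_in_goal


def make_history(
    pid: str,
    days: int,
    steps_fn,
    goal_fn=None,
    group: Group = Group.CONTROL,
    missing_days: set[int] = frozenset(),
) -> ParticipantHistory:
    """Deterministic history builder: steps_fn(day) -> steps, goal_fn(day) -> goal."""
    if goal_fn is None:
        goal_fn = lambda d: run_in_goal(d) if d <= 7 else 10_000
    records = []
    for d in range(1, days + 1):
        off = d in missing_days
        records.append(
            DailyRecord(
                participant_id=pid,
                study_day=d,
                goal=goal_fn(d),
                steps=None if off else int(steps_fn(d)),
                app_active=not off,
                group=group if d > 7 else Group.UNASSIGNED,
            )
        )
    return ParticipantHistory(participant_id=pid, records=records)


@pytest.fixture
def study_config() -> StudyConfig:
    return StudyConfig(seed=0)


@pytest.fixture
def small_dataset(study_config) -> TrialDataset:
    """2 controls + 2 intervention, 14 days, fully observed."""
    hists = [
        make_history("C01", 14, lambda d: 6000 + 10 * d, group=Group.CONTROL),
        make_history("C02", 14, lambda d: 7000 + 5 * d, group=Group.CONTROL),
        make_history("I01", 14, lambda d: 6500 + 20 * d, group=Group.INTERVENTION),
        make_history("I02", 14, lambda d: 8000 - 10 * d, group=Group.INTERVENTION),
    ]
    return TrialDataset(histories=hists, config=study_config)
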