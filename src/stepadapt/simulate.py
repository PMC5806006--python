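"""Synthetic two-arm trial simulator.

Generates per-participant daily step series responding to assigned goals
under the same two-regime behavioral model the adaptive engine fits
(engaged vs discouraged days, goal-attainment momentum, truncated-normal
day-to-day noise), plus app-nonuse missingness in geometric off-runs, and
the full trial flow: identical run-in ramp for everyone, 1:1 simple
randomization after day 7, control-arm constant goals vs intervention-arm
weekly adaptive updates.

Population heterogeneity is drawn from truncated-normal priors whose
defaults put the cohort's run-in daily steps near a 7300-step mean with a
between-participant SD near 2900, the scale typical of adult cohorts in
workplace step-goal trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy.special import ndtr, ndtri

from .adaptive import BehaviorParams, engagement_prob, weekly_update, _regime_means
from .core import DailyRecord, Group, ParticipantHistory, StudyConfig, TrialDataset
from .policies import GoalPolicy, control_goal, percentile_goal, run_in_goal

__all__ = [
    "ParamPrior",
    "PopulationPrior",
    "SimConfig",
    "sample_participant",
    "simulate_day",
    "simulate_days",
    "simulate_participant",
    "make_off_mask",
    "apply_missingness",
    "simulate_trial",
]


@dataclass(frozen=True)
class ParamPrior:
    """Truncated-normal prior for one behavioral parameter."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("prior sd must be >= 0")
        if self.lower > self.upper:
            raise ValueError("prior bounds inconsistent (lower > upper)")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            return float(np.clip(self.mean, self.lower, self.upper))
        a = ndtr((self.lower - self.mean) / self.sd)
        bb = ndtr((self.upper - self.mean) / self.sd)
        u = rng.random()
        return float(self.mean + self.sd * ndtri(a + u * (bb - a)))


@dataclass(frozen=True)
class PopulationPrior:
    """Cohort-level distribution of behavioral parameters and app nonuse.

    ``app_off_prob`` is the daily probability that an app-off run starts on
    an active day; ``app_off_mean_len`` is the mean (geometric) run length.
    """

    b: ParamPrior = ParamPrior(7300.0, 2850.0, 1000.0, 20000.0)
    sigma: ParamPrior = ParamPrior(1500.0, 400.0, 300.0, 5000.0)
    kappa0: ParamPrior = ParamPrior(0.5, 0.5, -2.0, 2.0)
    kappa1: ParamPrior = ParamPrior(2.0, 0.8, 0.0, 6.0)
    kappa2: ParamPrior = ParamPrior(1.0, 0.5, 0.0, 4.0)
    rho: ParamPrior = ParamPrior(0.3, 0.1, 0.0, 0.8)
    app_off_prob: float = 0.05
    app_off_mean_len: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.app_off_prob <= 1.0:
            raise ValueError("app_off_prob must lie in [0, 1]")
        if self.app_off_mean_len < 1.0:
            raise ValueError("app_off_mean_len must be >= 1")

    @classmethod
    def from_dict(cls, raw: dict) -> "PopulationPrior":
        kwargs: dict = {}
        for key, val in raw.items():
            if key in ("app_off_prob", "app_off_mean_len"):
                kwargs[key] = float(val)
            elif key in ("b", "sigma", "kappa0", "kappa1", "kappa2", "rho"):
                kwargs[key] = ParamPrior(**val) if isinstance(val, dict) else val
            else:
                raise ValueError(f"unknown PopulationPrior field: {key}")
        return cls(**kwargs)


@dataclass
class SimConfig:
    """Everything needed to simulate one trial, deterministically per seed.

    ``kappa2_shift``/``rho_shift`` perturb intervention-arm parameters for
    effect-size experiments; ``injected_slope`` adds a deterministic
    post-run-in trend (steps/day/day) to intervention-arm step totals, the
    knob effect-recovery harnesses use.  ``balanced_arms`` replaces simple
    randomization with a deterministic 50:50 split for calibration studies
    that need exact arm sizes.
    """

    n_participants: int
    study: StudyConfig = field(default_factory=StudyConfig)
    prior: PopulationPrior = field(default_factory=PopulationPrior)
    kappa2_shift: float = 0.0
    rho_shift: float = 0.0
    injected_slope: float = 0.0
    balanced_arms: bool = False
    control_both_arms: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        if "study" in raw and isinstance(raw["study"], dict):
            raw["study"] = StudyConfig.from_dict(raw["study"])
        if "prior" in raw and isinstance(raw["prior"], dict):
            raw["prior"] = PopulationPrior.from_dict(raw["prior"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**raw)


_PARAM_ORDER = ("b", "sigma", "kappa0", "kappa1", "kappa2", "rho")


def sample_participant(prior: PopulationPrior, rng: np.random.Generator) -> BehaviorParams:
    """Draw one participant's behavioral parameters from the prior."""
    draws = {name: getattr(prior, name).draw(rng) for name in _PARAM_ORDER}
    return BehaviorParams(**draws)


def _truncnorm_draw(mu: float, sigma: float, u: float) -> float:
    """Inverse-CDF draw from Normal(mu, sigma^2) truncated to [0, inf)."""
    a = ndtr(-mu / sigma)
    return mu + sigma * float(ndtri(a + u * (1.0 - a)))


def simulate_day(
    params: BehaviorParams, goal: int, m, rng: np.random.Generator
) -> int:
    """One day's realized steps: Bernoulli regime choice, truncated-normal draw."""
    pi = engagement_prob(params, goal, m)
    mu_e, mu_d = _regime_means(params, goal)
    engaged = rng.random() < pi
    mu = mu_e if engaged else mu_d
    x = _truncnorm_draw(mu, params.sigma, rng.random())
    return max(int(round(x)), 0)


def simulate_days(
    params: BehaviorParams, goal: int, m, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Vectorized batch of iid draws at fixed (goal, momentum)."""
    pi = engagement_prob(params, goal, m)
    mu_e, mu_d = _regime_means(params, goal)
    engaged = rng.random(n) < pi
    mu = np.where(engaged, mu_e, mu_d)
    a = ndtr(-mu / params.sigma)
    x = mu + params.sigma * ndtri(a + rng.random(n) * (1.0 - a))
    return np.maximum(np.rint(x), 0).astype(int)


def make_off_mask(
    days: int, q: float, mean_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask (True = app off) of geometric off-runs started at rate q."""
    off = np.zeros(days, dtype=bool)
    remaining = 0
    for d in range(days):
        if remaining > 0:
            off[d] = True
            remaining -= 1
        elif q > 0.0 and rng.random() < q:
            off[d] = True
            remaining = int(rng.geometric(1.0 / mean_len)) - 1
    return off


def apply_missingness(
    history: ParticipantHistory, prior: PopulationPrior, rng: np.random.Generator
) -> ParticipantHistory:
    """Mark app-off runs on an existing history; steps on off days become missing."""
    mask = make_off_mask(len(history.records), prior.app_off_prob, prior.app_off_mean_len, rng)
    records = []
    for rec, off in zip(history.records, mask):
        if off:
            rec = dataclasses.replace(rec, steps=None, app_active=False)
        records.append(rec)
    return ParticipantHistory(participant_id=history.participant_id, records=records)


def simulate_participant(
    params: BehaviorParams,
    policy: GoalPolicy,
    days: int,
    config: Optional[StudyConfig] = None,
    rng: Optional[np.random.Generator] = None,
    group: Group = Group.UNASSIGNED,
    off_mask: Optional[np.ndarray] = None,
    participant_id: str = "P001",
) -> ParticipantHistory:
    """Day-by-day simulation of one participant under a goal policy.

    Goals come from the policy (run-in ramp for everyone on days 1..7; the
    adaptive policy refits via :func:`stepadapt.adaptive.weekly_update` at
    each week boundary, seeing only the observed history).  The
    participant's internal momentum updates from *realized* attainment
    every day; app-off days (per ``off_mask``) are recorded with missing
    steps, so the engine and the percentile rule never see them.
    """
    if days < 7:
        raise ValueError("simulate at least the 7 run-in days")
    config = config or StudyConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if off_mask is None:
        off_mask = np.zeros(days, dtype=bool)

    history = ParticipantHistory(participant_id=participant_id)
    recent_attained: list[bool] = []
    schedule = None
    prev_goal = None

    for day in range(1, days + 1):
        if day <= config.run_in_days:
            goal = run_in_goal(day)
        elif policy.name == "run_in":
            raise ValueError("run_in policy covers days 1..7 only")
        elif policy.name == "control":
            goal = control_goal(day, config)
        elif policy.name == "percentile":
            try:
                goal = percentile_goal(
                    history, policy.percentile_p, policy.window, config, as_of_day=day - 1
                )
            except Exception:
                goal = prev_goal if prev_goal is not None else config.control_goal
        elif policy.name == "adaptive":
            if schedule is None or day > schedule.study_days[-1]:
                schedule = weekly_update(history, config)
            goal = schedule.goals[day - schedule.study_days[0]]
        else:  # pragma: no cover - GoalPolicy validates names
            raise ValueError(f"unknown policy {policy.name!r}")

        m = (
            sum(recent_attained[-7:]) / len(recent_attained[-7:])
            if recent_attained
            else 0.5
        )
        steps = simulate_day(params, goal, m, rng)
        recent_attained.append(steps >= goal)
        prev_goal = goal

        off = bool(off_mask[day - 1])
        rec_group = group if day > config.run_in_days else Group.UNASSIGNED
        history.records.append(
            DailyRecord(
                participant_id=participant_id,
                study_day=day,
                goal=goal,
                steps=None if off else steps,
                app_active=not off,
                group=rec_group,
            )
        )
    return history


def _assign_groups(sim: SimConfig, rng: np.random.Generator) -> list[Group]:
    if sim.balanced_arms:
        half = sim.n_participants // 2
        return [Group.CONTROL] * half + [Group.INTERVENTION] * (sim.n_participants - half)
    return [
        Group.INTERVENTION if rng.random() < sim.study.allocation_prob else Group.CONTROL
        for _ in range(sim.n_participants)
    ]


def simulate_trial(sim: SimConfig) -> TrialDataset:
    """Simulate the full two-arm trial; deterministic given ``sim.seed``.

    Every participant receives the identical run-in ramp; arms are assigned
    after day 7 by simple randomization (independent coin flips, so arm
    sizes may differ by chance).  Control-arm participants then follow the
    constant-goal policy, intervention-arm participants the weekly adaptive
    policy.  Each participant consumes an independent substream keyed by
    (seed, participant index), so adding participants never perturbs
    existing trajectories.
    """
    assign_rng = np.random.default_rng([sim.seed, 0])
    groups = _assign_groups(sim, assign_rng)
    study = sim.study
    days = study.total_days

    histories = []
    for i, grp in enumerate(groups):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng([sim.seed, i + 1])
        params = sample_participant(sim.prior, rng)
        if grp is Group.INTERVENTION and (sim.kappa2_shift or sim.rho_shift):
            params = BehaviorParams(
                b=params.b,
                sigma=params.sigma,
                kappa0=params.kappa0,
                kappa1=params.kappa1,
                kappa2=max(params.kappa2 + sim.kappa2_shift, 0.0),
                rho=float(np.clip(params.rho + sim.rho_shift, 0.0, 1.0)),
            )
        off_mask = make_off_mask(days, sim.prior.app_off_prob, sim.prior.app_off_mean_len, rng)
        if sim.control_both_arms or grp is Group.CONTROL:
            policy = GoalPolicy("control")
        else:
            policy = GoalPolicy("adaptive")
        hist = simulate_participant(
            params, policy, days, study, rng,
            group=grp, off_mask=off_mask, participant_id=pid,
        )
        if grp is Group.INTERVENTION and sim.injected_slope:
            hist = _inject_slope(hist, sim.injected_slope, study.run_in_days)
        histories.append(hist)
    return TrialDataset(histories=histories, config=study)


def _inject_slope(
    history: ParticipantHistory, slope: float, run_in_days: int
) -> ParticipantHistory:
    records = []
    for rec in history.records:
        if rec.steps is not None and rec.study_day > run_in_days:
            extra = int(round(slope * (rec.study_day - run_in_days)))
            rec = dataclasses.replace(rec, steps=max(rec.steps + extra, 0))
        records.append(rec)
    return ParticipantHistory(participant_id=history.participant_id, records=records)
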