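"""Adaptive personalized goal engine.

The engine mirrors the two-step structure of adaptive goal-setting
interventions: (1) fit a per-participant quantitative model predicting
daily steps as a function of the assigned goal and recent goal-attainment
momentum, from the participant's complete goal/step history; (2) choose
the coming week's seven goals to maximize the predicted total steps,
refreshed weekly.

Behavioral model
----------------
Each day the participant is either *engaged* (rises to the goal) or
*discouraged* (falls back toward, or below, baseline).  With baseline
``b`` and relative goal excess ``e = max((g - b)/b, 0)``:

* engagement probability  ``pi = logistic(kappa0 - kappa1*e + kappa2*m)``
  where ``m`` is the fraction of goals attained over the trailing seven
  observed days (a self-efficacy/momentum proxy);
* engaged days:     steps ~ Normal(max(g, b), sigma^2) truncated to >= 0;
* discouraged days: steps ~ Normal(b*(1 - rho*e), sigma^2) truncated to >= 0.

The model makes goals matter in both directions: overly ambitious goals
depress the engagement probability *and* the discouraged-day mean, while
attainable goals build momentum.  An interior "challenging yet realistic"
optimum emerges whenever ``kappa1 > 0`` and ``rho > 0``.

Parameters are estimated by maximum likelihood (multi-start bounded
local optimization); planning is exact dynamic programming over the goal
grid with momentum discretized to multiples of 1/7 and propagated by its
certainty-equivalent (expected-attainment) update.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize
from scipy.special import expit, log_ndtr, ndtr
from scipy.stats import qmc

from .core import InsufficientDataError, Group, ParticipantHistory, StudyConfig
from .policies import goal_attained, snap_to_grid

__all__ = [
    "BehaviorParams",
    "MomentumState",
    "FittedModel",
    "GoalPlan",
    "GoalSchedule",
    "PARAM_BOUNDS",
    "MIN_FIT_DAYS",
    "engagement_prob",
    "predict_expected_steps",
    "day_loglik",
    "fit_model",
    "plan_goals",
    "weekly_update",
    "trailing_momentum",
    "momentum_series",
    "truncnorm_mean",
]

#: Box bounds for maximum-likelihood estimation, in parameter order
#: (b, sigma, kappa0, kappa1, kappa2, rho).
PARAM_BOUNDS = (
    (500.0, 30_000.0),
    (100.0, 10_000.0),
    (-5.0, 5.0),
    (0.0, 10.0),
    (0.0, 10.0),
    (0.0, 1.0),
)

#: Minimum observed participant-days required before fitting.
MIN_FIT_DAYS = 14

_N_STARTS = 8
_MOMENTUM_DENOM = 7
_FALLBACK_RAMP = 250  # steps/day added by the fallback schedule
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class BehaviorParams:
    """Surrogate behavioral-model parameters for one participant."""

    b: float        # baseline steps/day
    sigma: float    # day-to-day step SD
    kappa0: float   # engagement intercept
    kappa1: float   # difficulty sensitivity (per unit relative goal excess)
    kappa2: float   # momentum weight
    rho: float      # fractional baseline loss per unit relative goal excess

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("baseline b must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("kappa1 and kappa2 must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([self.b, self.sigma, self.kappa0, self.kappa1, self.kappa2, self.rho])

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "BehaviorParams":
        return cls(*(float(x) for x in theta))


@dataclass(frozen=True)
class MomentumState:
    """Fraction of goals attained over the trailing 7 observed days."""

    m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")


@dataclass
class FittedModel:
    params: BehaviorParams
    loglik: float
    converged: bool
    n_obs: int
    sigma_at_bound: bool = False


@dataclass(frozen=True)
class GoalPlan:
    """A planned sequence of grid goals and its predicted total steps."""

    goals: tuple[int, ...]
    predicted_total_steps: float


@dataclass(frozen=True)
class GoalSchedule:
    """Seven goals stamped with the coming week's study days."""

    study_days: tuple[int, ...]
    goals: tuple[int, ...]
    source: str  # "model" or "fallback"
    model: Optional[FittedModel] = None
    plan: Optional[GoalPlan] = None


def _as_m(m: Union[MomentumState, float]) -> float:
    return m.m if isinstance(m, MomentumState) else float(m)


def engagement_prob(params: BehaviorParams, goal: float, m: Union[MomentumState, float]) -> float:
    """Probability of an engaged day: logistic in goal difficulty and momentum."""
    if goal <= 0:
        raise ValueError("goal must be positive")
    excess = max((goal - params.b) / params.b, 0.0)
    return float(expit(params.kappa0 - params.kappa1 * excess + params.kappa2 * _as_m(m)))


def truncnorm_mean(mu: float, sigma: float) -> float:
    """Mean of Normal(mu, sigma^2) truncated to [0, inf)."""
    z = mu / sigma
    # phi(z) / Phi(z), numerically safe far into the left tail
    ratio = math.exp(-0.5 * z * z - _LOG_SQRT_2PI - log_ndtr(z))
    return mu + sigma * ratio


def _regime_means(params: BehaviorParams, goal: float) -> tuple[float, float]:
    excess = max((goal - params.b) / params.b, 0.0)
    engaged = max(goal, params.b)
    discouraged = params.b * (1.0 - params.rho * excess)
    return engaged, discouraged


def predict_expected_steps(
    params: BehaviorParams, goal: float, m: Union[MomentumState, float]
) -> float:
    """Expected daily steps under the two-regime mixture at goal ``g``."""
    pi = engagement_prob(params, goal, m)
    mu_e, mu_d = _regime_means(params, goal)
    return pi * truncnorm_mean(mu_e, params.sigma) + (1.0 - pi) * truncnorm_mean(mu_d, params.sigma)


def _trunc_logpdf(y: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    z = (y - mu) / sigma
    return -0.5 * z * z - _LOG_SQRT_2PI - math.log(sigma) - log_ndtr(mu / sigma)


def day_loglik(
    params: BehaviorParams,
    goal: float,
    m: Union[MomentumState, float],
    steps: float,
) -> float:
    """Log density of one observed day under the two-component mixture."""
    if not (np.isfinite(goal) and np.isfinite(steps)):
        raise ValueError("goal and steps must be finite")
    if steps < 0:
        raise ValueError("steps must be non-negative")
    return float(
        _vector_loglik(
            params.to_array(),
            np.asarray([float(goal)]),
            np.asarray([float(steps)]),
            np.asarray([_as_m(m)]),
        )[0]
    )


def _vector_loglik(
    theta: np.ndarray, goals: np.ndarray, steps: np.ndarray, moms: np.ndarray
) -> np.ndarray:
    b, sigma, k0, k1, k2, rho = theta
    excess = np.maximum((goals - b) / b, 0.0)
    eta = k0 - k1 * excess + k2 * moms
    # log pi and log(1-pi) via softplus for numerical stability
    log_pi = -np.logaddexp(0.0, -eta)
    log_1mpi = -np.logaddexp(0.0, eta)
    mu_e = np.maximum(goals, b)
    mu_d = b * (1.0 - rho * excess)
    le = log_pi + _trunc_logpdf(steps, mu_e, sigma)
    ld = log_1mpi + _trunc_logpdf(steps, mu_d, sigma)
    return np.logaddexp(le, ld)


# ---------------------------------------------------------------------------
# Momentum from history
# ---------------------------------------------------------------------------

_DEFAULT_MOMENTUM = 0.5  # neutral prior before any observed day


def _attainments(history: ParticipantHistory) -> list[tuple[int, bool]]:
    out = []
    for r in history.records:
        a = goal_attained(r.steps, r.goal)
        if a is not None:
            out.append((r.study_day, a))
    return out


def trailing_momentum(history: ParticipantHistory, as_of_day: Optional[int] = None) -> MomentumState:
    """Attainment fraction over the last <= 7 observed days up to ``as_of_day``."""
    att = _attainments(history)
    if as_of_day is not None:
        att = [(d, a) for d, a in att if d <= as_of_day]
    tail = att[-_MOMENTUM_DENOM:]
    if not tail:
        return MomentumState(_DEFAULT_MOMENTUM)
    return MomentumState(sum(a for _, a in tail) / len(tail))


def momentum_series(history: ParticipantHistory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per observed day: (goal, steps, momentum entering that day).

    Momentum entering a day is the attainment fraction over the up-to-7
    observed days strictly before it (0.5 before any history exists).
    """
    goals, steps, moms = [], [], []
    recent: list[bool] = []
    for r in history.records:
        a = goal_attained(r.steps, r.goal)
        if a is None:
            continue
        m = sum(recent[-_MOMENTUM_DENOM:]) / len(recent[-_MOMENTUM_DENOM:]) if recent else _DEFAULT_MOMENTUM
        goals.append(float(r.goal))
        steps.append(float(r.steps))
        moms.append(m)
        recent.append(a)
    return np.asarray(goals), np.asarray(steps), np.asarray(moms)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _derive_seed(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def fit_model(
    history: ParticipantHistory,
    config: Optional[StudyConfig] = None,
    n_starts: int = _N_STARTS,
    seed: Optional[int] = None,
) -> FittedModel:
    """Maximum-likelihood fit of :class:`BehaviorParams` to one history.

    The objective is the sum of :func:`day_loglik` over all observed days,
    with momentum precomputed from trailing attainment.  Optimization uses
    ``n_starts`` Latin-hypercube starting points over the box bounds and
    L-BFGS-B; the multistart draw is seeded from ``seed`` (default: derived
    from ``config.seed`` and the participant id, so refits are deterministic).
    """
    config = config or StudyConfig()
    goals, steps, moms = momentum_series(history)
    n_obs = len(steps)
    if n_obs < MIN_FIT_DAYS:
        raise InsufficientDataError(
            f"need >= {MIN_FIT_DAYS} observed days to fit, have {n_obs}"
        )
    if seed is None:
        seed = _derive_seed(config.seed, history.participant_id, history.last_day())

    def nll(theta: np.ndarray) -> float:
        return -float(np.sum(_vector_loglik(theta, goals, steps, moms)))

    lo = np.array([b[0] for b in PARAM_BOUNDS])
    hi = np.array([b[1] for b in PARAM_BOUNDS])
    sampler = qmc.LatinHypercube(d=len(PARAM_BOUNDS), seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)
    # anchor one start at method-of-moments-ish values
    starts[0] = np.clip(
        [np.mean(steps), max(np.std(steps), 200.0), 0.0, 1.0, 1.0, 0.2], lo, hi
    )

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=PARAM_BOUNDS,
            options={"ftol": 1e-6, "gtol": 1e-5, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res

    params = BehaviorParams.from_array(best.x)
    loglik = -float(best.fun)
    converged = bool(best.success) and math.isfinite(loglik)
    sigma_at_bound = params.sigma <= PARAM_BOUNDS[1][0] * 1.0 + 1e-9
    return FittedModel(
        params=params, loglik=loglik, converged=converged,
        n_obs=n_obs, sigma_at_bound=sigma_at_bound,
    )


# ---------------------------------------------------------------------------
# Goal planning (exact DP over goal grid x discretized momentum)
# ---------------------------------------------------------------------------

def _snap_momentum_index(m: float) -> int:
    """Nearest multiple of 1/7, as an index 0..7."""
    return min(max(int(math.floor(m * _MOMENTUM_DENOM + 0.5)), 0), _MOMENTUM_DENOM)


def plan_goals(
    model: Union[FittedModel, BehaviorParams],
    m0: Union[MomentumState, float],
    config: Optional[StudyConfig] = None,
    horizon: int = 7,
) -> GoalPlan:
    """Choose the goal sequence maximizing predicted total steps.

    Solves ``max_{g_1..g_H} sum_t E[steps | g_t, m_t]`` exactly by backward
    dynamic programming, where momentum follows the certainty-equivalent
    update ``m_{t+1} = ((7-1) m_t + pi(g_t, m_t)) / 7`` snapped to the
    nearest multiple of 1/7.  Ties are broken toward the lower goal.
    """
    if isinstance(model, FittedModel):
        if not model.converged:
            raise ValueError("refusing to plan from an unconverged model")
        params = model.params
    else:
        params = model
    config = config or StudyConfig()
    grid = config.goal_grid()
    if not grid:
        raise ValueError("goal grid is empty; check goal_min/goal_max/goal_grid_step")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")

    n_m = _MOMENTUM_DENOM + 1
    n_g = len(grid)
    reward = np.empty((n_m, n_g))
    nxt = np.empty((n_m, n_g), dtype=int)
    for k in range(n_m):
        m = k / _MOMENTUM_DENOM
        for j, g in enumerate(grid):
            pi = engagement_prob(params, g, m)
            reward[k, j] = predict_expected_steps(params, g, m)
            nxt[k, j] = _snap_momentum_index(((_MOMENTUM_DENOM - 1) * m + pi) / _MOMENTUM_DENOM)

    value = np.zeros(n_m)
    choice = np.empty((horizon, n_m), dtype=int)
    for t in range(horizon - 1, -1, -1):
        new_value = np.empty(n_m)
        for k in range(n_m):
            best_v, best_j = -math.inf, 0
            for j in range(n_g):  # ascending grid + strict '>' == lower-goal tie-break
                v = reward[k, j] + value[nxt[k, j]]
                if v > best_v:
                    best_v, best_j = v, j
            new_value[k] = best_v
            choice[t, k] = best_j
        value = new_value

    k = _snap_momentum_index(_as_m(m0))
    total = float(value[k])
    goals = []
    for t in range(horizon):
        j = choice[t, k]
        goals.append(grid[j])
        k = nxt[k, j]
    return GoalPlan(goals=tuple(goals), predicted_total_steps=total)


def _fallback_schedule(
    history: ParticipantHistory, config: StudyConfig, study_days: tuple[int, ...]
) -> GoalSchedule:
    """Ramp of +250 steps/day from the trailing-7-day observed mean."""
    obs = [r.steps for r in history.observed_records()][-7:]
    base = float(np.mean(obs)) if obs else float(np.mean([3000, 3500, 4000, 4500, 5000, 5500, 6000]))
    goals = tuple(snap_to_grid(base + _FALLBACK_RAMP * (t + 1), config) for t in range(len(study_days)))
    return GoalSchedule(study_days=study_days, goals=goals, source="fallback")


def weekly_update(
    history: ParticipantHistory,
    config: Optional[StudyConfig] = None,
    week: Optional[int] = None,
) -> GoalSchedule:
    """Fit on all past data and plan the coming week's seven goals.

    ``week`` (1-based) selects the target week; by default the week
    following the last day in the history.  Deterministic given the
    history and ``config.seed``.  Control-arm histories are refused; if
    the history has fewer than 14 observed days or the fit fails, a
    fallback ramp schedule is returned instead.
    """
    config = config or StudyConfig()
    if history.group is Group.CONTROL:
        raise ValueError("adaptive goal updates apply to the intervention arm only")
    if history.last_day() < config.run_in_days:
        raise InsufficientDataError("history must cover at least the run-in period")

    if week is None:
        first_day = history.last_day() + 1
    else:
        first_day = 7 * (week - 1) + 1
    study_days = tuple(range(first_day, first_day + 7))

    if history.n_observed() < MIN_FIT_DAYS:
        return _fallback_schedule(history, config, study_days)
    try:
        model = fit_model(history, config)
    except (InsufficientDataError, ValueError):
        return _fallback_schedule(history, config, study_days)
    if not model.converged:
        return _fallback_schedule(history, config, study_days)

    m0 = trailing_momentum(history)
    plan = plan_goals(model, m0, config, horizon=7)
    return GoalSchedule(
        study_days=study_days, goals=plan.goals, source="model", model=model, plan=plan,
    )
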