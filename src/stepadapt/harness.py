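"""Replicated simulation studies: calibration and recovery harnesses.

These drive the simulator and the analysis pipeline across many seeded
replicates to measure operating characteristics — the type-I error of the
mixed-model interaction test under a null trial, recovery of an injected
between-arm effect, and recovery of the behavioral baseline parameter
from a single participant's history.  Tests and the acceptance script
both call these, so every reported rate is recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .adaptive import BehaviorParams, fit_model
from .analysis import LmmSpec, piecewise_lmm
from .core import DailyRecord, Group, ParticipantHistory, StudyConfig
from .simulate import PopulationPrior, SimConfig, simulate_day, simulate_trial

__all__ = [
    "null_calibration",
    "effect_recovery",
    "simulate_known_participant",
    "baseline_recovery",
]


def _calibration_config(
    n_per_arm: int, seed: int, injected_slope: float = 0.0
) -> SimConfig:
    return SimConfig(
        n_participants=2 * n_per_arm,
        study=StudyConfig(seed=seed),
        prior=PopulationPrior(),
        injected_slope=injected_slope,
        balanced_arms=True,
        control_both_arms=True,
        seed=seed,
    )


def null_calibration(
    n_reps: int = 500, n_per_arm: int = 20, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Type-I error of the interaction test under a null two-arm trial.

    Both arms follow the control goal policy with no arm effect, so any
    rejection of the arm-by-time interaction is a false positive.  Returns
    the rejection rate and the per-replicate p-values.
    """
    pvals = []
    for r in range(n_reps):
        sim = _calibration_config(n_per_arm, seed=int(seed) * 1_000_003 + r)
        dataset = simulate_trial(sim)
        fit = piecewise_lmm(dataset, LmmSpec())
        pvals.append(fit.interaction_pvalue)
    pvals = np.asarray(pvals, dtype=float)
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "n_reps": int(n_reps),
        "pvalues": pvals,
    }


def effect_recovery(
    slope_per_day: float = 20.0,
    n_reps: int = 100,
    n_per_arm: int = 20,
    seed: int = 0,
) -> dict:
    """Recovery of an injected post-run-in net step difference.

    A deterministic trend of ``slope_per_day`` steps/day/day is added to
    intervention-arm step totals after run-in; over a 10-week study this
    produces a true end-of-study net difference of ``slope_per_day * 63``
    steps.  Returns the replicate estimates and their mean bias.
    """
    true_net = slope_per_day * 63.0
    estimates = []
    for r in range(n_reps):
        sim = _calibration_config(
            n_per_arm, seed=int(seed) * 2_000_003 + r, injected_slope=slope_per_day
        )
        dataset = simulate_trial(sim)
        fit = piecewise_lmm(dataset, LmmSpec())
        estimates.append(fit.net_difference)
    estimates = np.asarray(estimates)
    mean_est = float(np.mean(estimates))
    return {
        "true_net_difference": true_net,
        "mean_estimate": mean_est,
        "relative_bias": (mean_est - true_net) / true_net if true_net else float("nan"),
        "estimates": estimates,
        "n_reps": int(n_reps),
    }


#: Goal cycle used by the single-participant recovery study: straddles the
#: baseline so both attainable and over-ambitious goals are exercised.
_RECOVERY_GOAL_CYCLE = (5000, 6000, 7000, 8000, 9000, 10000, 12000)


def simulate_known_participant(
    params: BehaviorParams,
    days: int,
    rng: np.random.Generator,
    goals: Optional[Sequence[int]] = None,
    participant_id: str = "K001",
) -> ParticipantHistory:
    """Simulate a history under a fixed repeating goal schedule.

    Used for parameter-recovery studies where the generating parameters
    are known and the goals must straddle the baseline to identify the
    difficulty and discouragement terms.
    """
    cycle = tuple(goals) if goals is not None else _RECOVERY_GOAL_CYCLE
    hist = ParticipantHistory(participant_id=participant_id)
    recent: list[bool] = []
    for day in range(1, days + 1):
        goal = cycle[(day - 1) % len(cycle)]
        m = sum(recent[-7:]) / len(recent[-7:]) if recent else 0.5
        steps = simulate_day(params, goal, m, rng)
        recent.append(steps >= goal)
        hist.records.append(
            DailyRecord(
                participant_id=participant_id, study_day=day, goal=goal,
                steps=steps, app_active=True, group=Group.INTERVENTION,
            )
        )
    return hist


def baseline_recovery(
    n_seeds: int = 20,
    days: int = 70,
    seed: int = 0,
    true_params: Optional[BehaviorParams] = None,
) -> dict:
    """Median relative error of the fitted baseline across replicate histories."""
    truth = true_params or BehaviorParams(
        b=7000.0, sigma=1500.0, kappa0=0.5, kappa1=2.0, kappa2=1.0, rho=0.3
    )
    b_errors, sigma_errors = [], []
    for r in range(n_seeds):
        rng = np.random.default_rng([int(seed), 77, r])
        hist = simulate_known_participant(truth, days, rng)
        model = fit_model(hist, seed=int(seed) * 3_000_017 + r)
        b_errors.append(abs(model.params.b - truth.b) / truth.b)
        sigma_errors.append(abs(model.params.sigma - truth.sigma) / truth.sigma)
    return {
        "median_rel_error_b": float(np.median(b_errors)),
        "median_rel_error_sigma": float(np.median(sigma_errors)),
        "b_errors": np.asarray(b_errors),
        "n_seeds": int(n_seeds),
    }
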