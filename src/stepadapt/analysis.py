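"""Statistical pipeline for two-arm adaptive-goal trials.

Implements the analysis set standard for this design: a piecewise
linear-growth mixed model for daily steps (random intercept and slope per
participant, fixed effects of time, arm, and their interaction, with a
slope change at the run-in/intervention knot), an analogous mixed model
for the binary goal-attainment outcome, run-in adjustment of weekly
means, 7-day moving averages, frequent-user classification for the
per-protocol subset, Student t tests, and exact (noncentral-t) power and
sample-size calculations.

Missing outcome days stay missing and are handled by the likelihood —
no explicit imputation, and in particular no last-observation-carried-
forward, which would inflate late step counts.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .core import Group, InsufficientDataError, TrialDataset, ParticipantHistory
from .policies import goal_attained

__all__ = [
    "LmmSpec",
    "EffectEstimate",
    "LmmFit",
    "PowerSpec",
    "TTestResult",
    "SampleSizeResult",
    "trial_frame",
    "piecewise_lmm",
    "attainment_glmm",
    "weekly_means",
    "runin_adjust",
    "moving_average",
    "classify_frequent_users",
    "per_protocol_subset",
    "two_sample_ttest",
    "power_two_sample",
    "sample_size",
]

FREQUENT = "frequent"
NONFREQUENT = "nonfrequent"

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class LmmSpec:
    """What to fit: outcome, knot, time coding, analysis population."""

    outcome: str = "daily_steps"       # or "attained"
    knot_day: int = 7
    time_unit: str = "day"             # repeated measures daily or week-aggregated
    population: str = "ITT"            # or "PP"
    link: str = "logit"                # binary outcome link; "linear" for sensitivity

    def __post_init__(self) -> None:
        if self.outcome not in ("daily_steps", "attained"):
            raise ValueError("outcome must be 'daily_steps' or 'attained'")
        if self.time_unit not in ("day", "week"):
            raise ValueError("time_unit must be 'day' or 'week'")
        if self.population not in ("ITT", "PP"):
            raise ValueError("population must be 'ITT' or 'PP'")
        if self.link not in ("logit", "linear"):
            raise ValueError("link must be 'logit' or 'linear'")
        if self.knot_day < 1:
            raise ValueError("knot_day must be >= 1")


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: Optional[float] = None


@dataclass
class LmmFit:
    """Fixed effects, variance components, and the derived net difference."""

    outcome: str
    scale: str                                # "steps" or "probability"
    fixed_effects: dict[str, EffectEstimate]
    group_coefficients: dict[str, float]      # per-arm intercept offset
    net_difference: float
    net_ci: tuple[float, float]
    interaction_pvalue: Optional[float]
    re_intercept_sd: Optional[float]
    re_slope_sd: Optional[float]
    resid_sd: Optional[float]
    n_obs: int
    n_participants: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["net_ci"] = list(self.net_ci)
        return out


def trial_frame(dataset: TrialDataset, knot_day: int = 7, time_unit: str = "day") -> pd.DataFrame:
    """Long-format analysis frame with piecewise time coding.

    Time is measured in weeks (``t = study_day / 7``) so slopes read as
    steps/week; ``s1``/``s2`` are the pre-/post-knot segments of ``t`` and
    ``grp`` codes the intervention arm as 1.  Only observed days appear.
    """
    df = dataset.to_frame()
    arm = {h.participant_id: h.group.value for h in dataset.histories}
    df["arm"] = df["participant_id"].map(arm)
    df = df[df["arm"].isin(["control", "intervention"])].copy()
    df["attained"] = [
        None if pd.isna(s) else float(s >= g) for s, g in zip(df["steps"], df["goal"])
    ]
    df = df[df["steps"].notna()].copy()
    df["grp"] = (df["arm"] == "intervention").astype(float)
    if time_unit == "week":
        df["week"] = (df["study_day"] - 1) // 7 + 1
        df = (
            df.groupby(["participant_id", "arm", "grp", "week"], as_index=False)
            .agg(steps=("steps", "mean"), attained=("attained", "mean"))
        )
        df["t"] = df["week"].astype(float)
    else:
        df["t"] = df["study_day"] / 7.0
    knot_w = knot_day / 7.0
    df["s1"] = np.minimum(df["t"], knot_w)
    df["s2"] = np.maximum(df["t"] - knot_w, 0.0)
    df["pid"] = df["participant_id"]
    return df


def _fixed_formula(df: pd.DataFrame, outcome: str) -> str:
    # with week-aggregated time the pre-knot segment is a single point, so
    # s1 is constant and must drop out of the fixed design
    terms = ["s1", "s2", "grp", "s2:grp"] if df["s1"].nunique() > 1 else ["s2", "grp", "s2:grp"]
    return f"{outcome} ~ " + " + ".join(terms)


def _check_arms(dataset: TrialDataset) -> None:
    n_c = len(dataset.arm(Group.CONTROL))
    n_i = len(dataset.arm(Group.INTERVENTION))
    if n_c < 2 or n_i < 2:
        raise InsufficientDataError(
            f"need >= 2 participants per arm, have control={n_c}, intervention={n_i}"
        )


def piecewise_lmm(dataset: TrialDataset, spec: Optional[LmmSpec] = None) -> LmmFit:
    """Piecewise linear-growth LMM for daily steps (REML).

    Fixed effects: intercept, pre-knot slope ``s1``, post-knot slope
    ``s2``, arm, and the arm-by-post-knot-slope interaction.  Random
    intercept and slope per participant.  The headline quantity is the
    end-of-study net between-group difference: the interaction slope times
    the post-knot duration, with a Wald 95% CI.  If the full random
    structure fails, the model refits with a random intercept only and
    says so in ``notes``.
    """
    spec = spec or LmmSpec()
    _check_arms(dataset)
    df = trial_frame(dataset, spec.knot_day, spec.time_unit)

    notes: list[str] = []
    converged = True
    result = None
    for re_formula in ("~t", "~1"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    _fixed_formula(df, "steps"), df, groups=df["pid"], re_formula=re_formula
                )
                result = model.fit(reml=True, method="lbfgs")
            if not result.converged:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = model.fit(reml=True)
            if result.converged:
                if re_formula == "~1":
                    notes.append("random slope dropped (full covariance did not converge)")
                break
        except (np.linalg.LinAlgError, ValueError):
            result = None
            continue
    if result is None:
        raise RuntimeError("mixed model failed to fit under all random-effect structures")
    if not result.converged:
        converged = False
        notes.append("optimizer did not report convergence; estimates are provisional")

    fe_names = [n for n in ["Intercept", "s1", "s2", "grp", "s2:grp"]
                if n in result.params.index]
    fixed: dict[str, EffectEstimate] = {}
    for name in fe_names:
        est = float(result.params[name])
        se = float(result.bse[name])
        fixed[name] = EffectEstimate(
            estimate=est, se=se,
            ci_low=est - _Z975 * se, ci_high=est + _Z975 * se,
            pvalue=float(result.pvalues[name]),
        )

    max_day = max(h.last_day() for h in dataset.histories)
    if spec.time_unit == "week":
        post_span = float((max_day - 1) // 7 + 1 - spec.knot_day / 7.0)
    else:
        post_span = (max_day - spec.knot_day) / 7.0
    inter = fixed["s2:grp"]
    net = inter.estimate * post_span
    net_ci = (inter.ci_low * post_span, inter.ci_high * post_span)

    cov_re = np.asarray(result.cov_re)
    re_int_sd = math.sqrt(max(cov_re[0, 0], 0.0))
    re_slope_sd = math.sqrt(max(cov_re[1, 1], 0.0)) if cov_re.shape[0] > 1 else None
    return LmmFit(
        outcome="daily_steps",
        scale="steps",
        fixed_effects=fixed,
        group_coefficients={"control": 0.0, "intervention": fixed["grp"].estimate},
        net_difference=net,
        net_ci=net_ci,
        interaction_pvalue=inter.pvalue,
        re_intercept_sd=re_int_sd,
        re_slope_sd=re_slope_sd,
        resid_sd=math.sqrt(float(result.scale)),
        n_obs=int(len(df)),
        n_participants=int(df["pid"].nunique()),
        converged=converged,
        notes=notes,
    )


def _marginal_prob(eta: np.ndarray, tau: float, gh: int = 31) -> np.ndarray:
    """E[expit(eta + tau*Z)], Z~N(0,1), by Gauss-Hermite quadrature."""
    if tau <= 0:
        return 1.0 / (1.0 + np.exp(-eta))
    x, w = np.polynomial.hermite_e.hermegauss(gh)
    z = np.add.outer(np.atleast_1d(eta), tau * x)
    p = 1.0 / (1.0 + np.exp(-z))
    return p @ (w / w.sum())


def attainment_glmm(dataset: TrialDataset, spec: Optional[LmmSpec] = None) -> LmmFit:
    """Mixed model for daily goal attainment (binary outcome).

    Same fixed structure as the steps model.  With the default logit link
    the model is a Bayesian binomial mixed GLM (variational fit, weakly
    informative priors — which also regularizes complete separation) with
    random intercept and random slope; the net difference is reported on
    the probability scale as a difference-in-differences of marginal
    (random-effect-integrated) attainment probabilities between run-in and
    end of study, with a CI from sampling the fixed-effect posterior.
    ``link='linear'`` instead fits a linear-probability LMM whose
    interaction slope is already on the probability scale.
    """
    spec = spec or LmmSpec(outcome="attained")
    _check_arms(dataset)
    df = trial_frame(dataset, spec.knot_day, spec.time_unit)
    df = df[df["attained"].notna()].copy()
    df["attained"] = df["attained"].astype(float)
    n_obs = int(len(df))
    n_part = int(df["pid"].nunique())

    max_day = max(h.last_day() for h in dataset.histories)
    knot_w = spec.knot_day / 7.0
    t_end = max_day / 7.0 if spec.time_unit == "day" else float((max_day - 1) // 7 + 1)
    post_span = t_end - knot_w

    if df["attained"].nunique() < 2:
        value = float(df["attained"].iloc[0])
        return LmmFit(
            outcome="attained", scale="probability", fixed_effects={},
            group_coefficients={"control": 0.0, "intervention": 0.0},
            net_difference=0.0, net_ci=(0.0, 0.0), interaction_pvalue=None,
            re_intercept_sd=None, re_slope_sd=None, resid_sd=None,
            n_obs=n_obs, n_participants=n_part, converged=False,
            notes=[f"degenerate outcome: attainment is {value:g} on every observed day"],
        )

    if spec.link == "linear":
        fit = _linear_probability_fit(df, post_span)
        fit.n_obs, fit.n_participants = n_obs, n_part
        return fit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(
            _fixed_formula(df, "attained"),
            {"icept": "0 + C(pid)", "slope": "0 + C(pid):t"},
            df,
        )
        # the variational optimizer draws its starting point from the global
        # legacy RNG; pin it so the fit is a deterministic function of the data
        state = np.random.get_state()
        np.random.seed(20_259)
        try:
            result = model.fit_vb()
        finally:
            np.random.set_state(state)

    fe_names = list(model.exog_names)
    fe_mean = np.asarray(result.fe_mean)
    fe_sd = np.asarray(result.fe_sd)
    fixed = {
        name: EffectEstimate(
            estimate=float(mu), se=float(sd),
            ci_low=float(mu - _Z975 * sd), ci_high=float(mu + _Z975 * sd),
        )
        for name, mu, sd in zip(fe_names, fe_mean, fe_sd)
    }
    tau_icept, tau_slope = (float(np.exp(v)) for v in result.vcp_mean)

    def net_from(beta: np.ndarray) -> float:
        idx = {n: i for i, n in enumerate(fe_names)}

        def eta(s2: float, grp: float, t: float) -> float:
            x = np.zeros(len(fe_names))
            x[idx["Intercept"]] = 1.0
            if "s1" in idx:
                x[idx["s1"]] = knot_w
            x[idx["s2"]] = s2
            x[idx["grp"]] = grp
            x[idx["s2:grp"]] = s2 * grp
            return float(x @ beta), t

        vals = {}
        for label, (s2, grp, t) in {
            "c0": (0.0, 0.0, knot_w), "c1": (post_span, 0.0, t_end),
            "i0": (0.0, 1.0, knot_w), "i1": (post_span, 1.0, t_end),
        }.items():
            e, tt = eta(s2, grp, t)
            tau = math.hypot(tau_icept, tau_slope * tt)
            vals[label] = float(_marginal_prob(np.array([e]), tau)[0])
        return (vals["i1"] - vals["i0"]) - (vals["c1"] - vals["c0"])

    net = net_from(fe_mean)
    rng = np.random.default_rng(0)  # fixed: CI of a deterministic fit
    draws = rng.normal(fe_mean, fe_sd, size=(1000, len(fe_mean)))
    net_draws = np.array([net_from(b) for b in draws])
    net_ci = (float(np.quantile(net_draws, 0.025)), float(np.quantile(net_draws, 0.975)))
    inter = fixed["s2:grp"]
    z = inter.estimate / inter.se if inter.se > 0 else 0.0
    pval = 2.0 * float(stats.norm.sf(abs(z)))

    return LmmFit(
        outcome="attained", scale="probability", fixed_effects=fixed,
        group_coefficients={"control": 0.0, "intervention": fixed["grp"].estimate},
        net_difference=float(net), net_ci=net_ci, interaction_pvalue=pval,
        re_intercept_sd=tau_icept, re_slope_sd=tau_slope, resid_sd=None,
        n_obs=n_obs, n_participants=n_part, converged=True, notes=[],
    )


def _linear_probability_fit(df: pd.DataFrame, post_span: float) -> LmmFit:
    notes = ["linear-probability sensitivity model"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(_fixed_formula(df, "attained"), df, groups=df["pid"], re_formula="~t")
        result = model.fit(reml=True, method="lbfgs")
    fixed = {}
    for name in [n for n in ["Intercept", "s1", "s2", "grp", "s2:grp"]
                 if n in result.params.index]:
        est, se = float(result.params[name]), float(result.bse[name])
        fixed[name] = EffectEstimate(est, se, est - _Z975 * se, est + _Z975 * se,
                                     float(result.pvalues[name]))
    inter = fixed["s2:grp"]
    return LmmFit(
        outcome="attained", scale="probability", fixed_effects=fixed,
        group_coefficients={"control": 0.0, "intervention": fixed["grp"].estimate},
        net_difference=inter.estimate * post_span,
        net_ci=(inter.ci_low * post_span, inter.ci_high * post_span),
        interaction_pvalue=inter.pvalue,
        re_intercept_sd=math.sqrt(max(np.asarray(result.cov_re)[0, 0], 0.0)),
        re_slope_sd=None, resid_sd=math.sqrt(float(result.scale)),
        n_obs=0, n_participants=0, converged=bool(result.converged), notes=notes,
    )


def weekly_means(dataset: TrialDataset, value: str = "steps") -> pd.DataFrame:
    """Per-arm weekly means over observed participant-days (no imputation).

    ``value`` selects the summarized quantity: ``steps``, ``goal``, or
    ``attained`` (the fraction of observed days whose goal was met).  A
    week with no observed days in an arm is reported as missing, not 0.
    """
    if value not in ("steps", "goal", "attained"):
        raise ValueError("value must be 'steps', 'goal' or 'attained'")
    rows = []
    for hist in dataset.histories:
        arm = hist.group.value
        for rec in hist.records:
            week = dataset.config.week_of_day(rec.study_day)
            if value == "goal":
                v, ok = float(rec.goal), True
            elif rec.steps is None:
                v, ok = np.nan, False
            elif value == "steps":
                v, ok = float(rec.steps), True
            else:
                v, ok = float(goal_attained(rec.steps, rec.goal)), True
            rows.append((arm, week, v, ok))
    df = pd.DataFrame(rows, columns=["group", "week", "value", "observed"])
    out = (
        df[df["observed"]]
        .groupby(["group", "week"], as_index=False)
        .agg(mean=("value", "mean"), n_obs=("value", "size"))
    )
    # reinstate empty weeks as missing rows
    weeks = range(1, dataset.config.total_weeks + 1)
    full = pd.MultiIndex.from_product(
        [sorted(df["group"].unique()), weeks], names=["group", "week"]
    ).to_frame(index=False)
    out = full.merge(out, on=["group", "week"], how="left")
    out["n_obs"] = out["n_obs"].fillna(0).astype(int)
    return out


def runin_adjust(weekly: pd.DataFrame, fit: LmmFit, run_in_week: int = 1) -> pd.DataFrame:
    """Shift each arm's run-in weekly mean by that arm's model coefficient.

    Makes the arms comparable at the reference week: the run-in row for
    each arm gains the arm's intercept offset from the mixed model; all
    other rows are unchanged.
    """
    arms = set(weekly["group"].unique()) - {"unassigned"}
    unknown = arms - set(fit.group_coefficients)
    if unknown:
        raise ValueError(f"arms {sorted(unknown)} missing from the fit's group coefficients")
    out = weekly.copy()
    mask = out["week"] == run_in_week
    out.loc[mask, "mean"] = out.loc[mask].apply(
        lambda r: r["mean"] + fit.group_coefficients.get(r["group"], 0.0), axis=1
    )
    return out


def moving_average(series: Sequence[float], window: int = 7) -> np.ndarray:
    """Trailing moving average over full windows; missing values are skipped.

    Returns an array of length ``len(series) - window + 1``.  Within each
    window the mean is over the observed (non-missing) subset; a window
    with no observed values yields NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.array([np.nan if v is None else float(v) for v in series], dtype=float)
    if len(x) < window:
        raise ValueError(f"series length {len(x)} shorter than window {window}")
    out = np.empty(len(x) - window + 1)
    for i in range(len(out)):
        chunk = x[i : i + window]
        obs = chunk[~np.isnan(chunk)]
        out[i] = obs.mean() if len(obs) else np.nan
    return out


def _max_off_run(history: ParticipantHistory) -> int:
    longest = run = 0
    for rec in history.records:
        run = run + 1 if not rec.app_active else 0
        longest = max(longest, run)
    return longest


def classify_frequent_users(dataset: TrialDataset, threshold: int = 7) -> dict[str, str]:
    """Label each participant frequent/nonfrequent by consecutive app nonuse.

    A participant is nonfrequent iff the app was unused for ``threshold``
    (default 7) or more consecutive days at any point in the study.
    """
    return {
        h.participant_id: (NONFREQUENT if _max_off_run(h) >= threshold else FREQUENT)
        for h in dataset.histories
    }


def per_protocol_subset(dataset: TrialDataset) -> TrialDataset:
    """Restrict to frequent app users (the per-protocol population)."""
    labels = classify_frequent_users(dataset)
    keep = [h for h in dataset.histories if labels[h.participant_id] == FREQUENT]
    if not keep:
        raise InsufficientDataError("per-protocol subset is empty: no frequent users")
    return TrialDataset(histories=keep, config=dataset.config)


@dataclass(frozen=True)
class TTestResult:
    t: float
    pvalue: float
    mean_difference: float
    ci_low: float
    ci_high: float
    df: float


def two_sample_ttest(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sided Student t test with a 95% CI on the difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    nx, ny = len(x), len(y)
    dof = nx + ny - 2
    diff = float(x.mean() - y.mean())
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / dof
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 1.0, 0.0, 0.0, 0.0, dof)
        return TTestResult(math.copysign(math.inf, diff), 0.0, diff, diff, diff, dof)
    se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    tc = float(stats.t.ppf(0.975, dof))
    return TTestResult(t, p, diff, diff - tc * se, diff + tc * se, dof)


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs for the two-sample t-test power calculation."""

    delta: float            # between-group difference, steps/day
    sd: float               # pooled SD, steps/day
    alpha: float = 0.05
    power: float = 0.80
    attrition: float = 0.0  # expected loss to follow-up, as a fraction

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if not 0.0 <= self.attrition < 1.0:
            raise ValueError("attrition must lie in [0, 1)")


def power_two_sample(n_per_group: int, spec: PowerSpec) -> float:
    """Exact power of the two-sided two-sample t test (noncentral t)."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    dof = 2 * n_per_group - 2
    ncp = abs(spec.delta) / (spec.sd * math.sqrt(2.0 / n_per_group))
    crit = stats.t.ppf(1.0 - spec.alpha / 2.0, dof)
    return float(stats.nct.sf(crit, dof, ncp) + stats.nct.cdf(-crit, dof, ncp))


@dataclass(frozen=True)
class SampleSizeResult:
    n_per_group: int           # smallest n reaching the power target
    n_inflated: int            # after dividing by (1 - attrition), rounded up
    achieved_power: float


def sample_size(spec: PowerSpec, n_max: int = 100_000) -> SampleSizeResult:
    """Smallest per-group n meeting the power target, plus attrition inflation."""
    for n in range(2, n_max + 1):
        pw = power_two_sample(n, spec)
        if pw >= spec.power:
            inflated = math.ceil(n / (1.0 - spec.attrition))
            return SampleSizeResult(n_per_group=n, n_inflated=inflated, achieved_power=pw)
    raise ValueError("no sample size up to n_max reaches the power target")
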