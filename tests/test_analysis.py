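import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

from stepadapt.analysis import (
    FREQUENT,
    NONFREQUENT,
    EffectEstimate,
    LmmFit,
    LmmSpec,
    PowerSpec,
    attainment_glmm,
    classify_frequent_users,
    moving_average,
    per_protocol_subset,
    piecewise_lmm,
    power_two_sample,
    runin_adjust,
    sample_size,
    two_sample_ttest,
    weekly_means,
)
from stepadapt.core import (
    DailyRecord,
    Group,
    InsufficientDataError,
    StudyConfig,
    ParticipantHistory,
    TrialDataset,
)

from conftest import make_history
from oracles import brute_force_max_run


def _dataset(hists, cfg=None):
    return TrialDataset(histories=list(hists), config=cfg or StudyConfig())


class TestPiecewiseLmm:
    def test_symmetric_arms_give_zero_interaction(self):
        # identical trajectories in both arms: any nonzero arm effect would
        # break the label-swap symmetry of the estimator
        def traj(offset):
            return lambda d: 6000 + 30 * d + (50 if d % 2 == 0 else -50) + offset

        hists = [
            make_history("C1", 70, traj(0), group=Group.CONTROL),
            make_history("C2", 70, traj(400), group=Group.CONTROL),
            make_history("I1", 70, traj(0), group=Group.INTERVENTION),
            make_history("I2", 70, traj(400), group=Group.INTERVENTION),
        ]
        fit = piecewise_lmm(_dataset(hists))
        assert abs(fit.fixed_effects["s2:grp"].estimate) < 1e-3
        assert abs(fit.fixed_effects["grp"].estimate) < 1e-3
        assert abs(fit.net_difference) < 1e-2

    def test_known_linear_divergence_recovered(self):
        # intervention gains exactly 140 steps/week post-knot -> net 1260
        rng = np.random.default_rng(0)

        def make(pid, grp, gain):
            base = 7000 + rng.normal(0, 500)
            return make_history(
                pid, 70,
                lambda d: base + gain * max(d - 7, 0) + rng.normal(0, 300),
                group=grp,
            )

        hists = [make(f"C{i}", Group.CONTROL, 0.0) for i in range(6)]
        hists += [make(f"I{i}", Group.INTERVENTION, 20.0) for i in range(6)]
        fit = piecewise_lmm(_dataset(hists))
        assert fit.net_difference == pytest.approx(1260, rel=0.05)
        assert fit.net_ci[0] < fit.net_difference < fit.net_ci[1]

    def test_week_aggregated_time_smoke(self):
        rng = np.random.default_rng(1)
        hists = [
            make_history(f"P{i}", 70, lambda d: 7000 + rng.normal(0, 800),
                         group=Group.CONTROL if i < 3 else Group.INTERVENTION)
            for i in range(6)
        ]
        fit = piecewise_lmm(_dataset(hists), LmmSpec(time_unit="week"))
        assert math.isfinite(fit.net_difference)
        assert fit.n_participants == 6

    def test_too_few_participants_per_arm_rejected(self, small_dataset):
        ds = _dataset(small_dataset.histories[:3])
        with pytest.raises(InsufficientDataError):
            piecewise_lmm(ds)


def _binary_dataset(attained: np.ndarray, groups: list[Group]) -> TrialDataset:
    """Encode a (participants x days) attainment matrix as a dataset."""
    hists = []
    for i, grp in enumerate(groups):
        recs = []
        for d in range(1, attained.shape[1] + 1):
            a = attained[i, d - 1]
            recs.append(DailyRecord(
                participant_id=f"P{i:02d}", study_day=d, goal=10_000,
                steps=12_000 if a else 5_000, app_active=True,
                group=grp if d > 7 else Group.UNASSIGNED,
            ))
        hists.append(ParticipantHistory(participant_id=f"P{i:02d}", records=recs))
    return _dataset(hists)


def _marginal_inverse(p_target: float, tau: float) -> float:
    x, w = np.polynomial.hermite_e.hermegauss(31)
    w = w / w.sum()

    def marg(eta):
        return float(np.sum(w / (1 + np.exp(-(eta + tau * x))))) - p_target

    return brentq(marg, -10, 10)


class TestAttainmentGlmm:
    def test_degenerate_all_attained_reported_not_crashed(self):
        attained = np.ones((6, 21), dtype=bool)
        ds = _binary_dataset(attained, [Group.CONTROL] * 3 + [Group.INTERVENTION] * 3)
        fit = attainment_glmm(ds)
        assert not fit.converged
        assert any("degenerate" in n for n in fit.notes)

    def test_label_swap_negates_net_difference_linear_link(self):
        rng = np.random.default_rng(5)
        attained = rng.random((10, 70)) < np.linspace(0.8, 0.3, 70)
        attained[5:, 7:] |= rng.random((5, 63)) < 0.25
        groups = [Group.CONTROL] * 5 + [Group.INTERVENTION] * 5
        swapped = [Group.INTERVENTION] * 5 + [Group.CONTROL] * 5
        spec = LmmSpec(outcome="attained", link="linear")
        f1 = attainment_glmm(_binary_dataset(attained, groups), spec)
        f2 = attainment_glmm(_binary_dataset(attained, swapped), spec)
        assert f1.net_difference == pytest.approx(-f2.net_difference, rel=1e-3, abs=1e-6)

    def test_probability_scale_difference_recovered(self):
        # marginal attainment 0.70 at run-in in both arms, declining to 0.30
        # (control) vs 0.45 (intervention): true DiD on the probability
        # scale is +0.15; the logit GLMM's marginalized estimate should
        # land within 0.05 on average
        tau = 0.5
        eta_runin = _marginal_inverse(0.70, tau)
        eta_c = _marginal_inverse(0.30, tau)
        eta_i = _marginal_inverse(0.45, tau)
        n_per_arm, days, reps = 15, 70, 12
        groups = [Group.CONTROL] * n_per_arm + [Group.INTERVENTION] * n_per_arm
        nets = []
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            u = rng.normal(0, tau, size=2 * n_per_arm)
            t = np.arange(1, days + 1) / 7.0
            s2 = np.maximum(t - 1.0, 0.0)
            attained = np.empty((2 * n_per_arm, days), dtype=bool)
            for i in range(2 * n_per_arm):
                eta_end = eta_i if groups[i] is Group.INTERVENTION else eta_c
                eta = eta_runin + (eta_end - eta_runin) * s2 / 9.0 + u[i]
                attained[i] = rng.random(days) < 1.0 / (1.0 + np.exp(-eta))
            fit = attainment_glmm(_binary_dataset(attained, groups))
            nets.append(fit.net_difference)
        assert np.mean(nets) == pytest.approx(0.15, abs=0.05)


class TestWeeklyMeans:
    def test_constant_series_every_week(self):
        ds = _dataset([
            make_history("P1", 70, lambda d: 8000, group=Group.CONTROL),
            make_history("P2", 70, lambda d: 8000, group=Group.CONTROL),
        ])
        wk = weekly_means(ds)
        assert (wk["mean"] == 8000).all()
        assert list(wk["week"]) == list(range(1, 11))

    def test_hand_computed_two_participant_fixture(self):
        ds = _dataset([
            make_history("P1", 14, lambda d: 1000 * d, group=Group.CONTROL),
            make_history("P2", 14, lambda d: 2000, group=Group.CONTROL),
        ], StudyConfig(total_weeks=2))
        wk = weekly_means(ds)
        # week 1: mean of {1000..7000} and {2000 x7} = (28000 + 14000)/14
        w1 = wk[(wk["week"] == 1) & (wk["group"] == "control")]["mean"].iloc[0]
        assert w1 == pytest.approx((28000 + 14000) / 14)
        w2 = wk[(wk["week"] == 2) & (wk["group"] == "control")]["mean"].iloc[0]
        assert w2 == pytest.approx((sum(range(8, 15)) * 1000 + 14000) / 14)

    def test_all_missing_week_reported_missing_not_zero(self):
        ds = _dataset([
            make_history("P1", 21, lambda d: 6000, group=Group.CONTROL,
                         missing_days=set(range(8, 15))),
            make_history("P2", 21, lambda d: 6000, group=Group.CONTROL,
                         missing_days=set(range(8, 15))),
        ], StudyConfig(total_weeks=3))
        wk = weekly_means(ds)
        w2 = wk[(wk["week"] == 2) & (wk["group"] == "control")]
        assert math.isnan(w2["mean"].iloc[0])
        assert w2["n_obs"].iloc[0] == 0

    def test_attainment_fractions(self):
        ds = _dataset([
            make_history("P1", 14, lambda d: 12_000 if d % 2 == 0 else 1000,
                         group=Group.CONTROL),
            make_history("P2", 14, lambda d: 12_000, group=Group.CONTROL),
        ], StudyConfig(total_weeks=2))
        wk = weekly_means(ds, "attained")
        w2 = wk[(wk["week"] == 2) & (wk["group"] == "control")]["mean"].iloc[0]
        # week 2 goals are 10000: P1 attains on even days (4 of 7), P2 always
        assert w2 == pytest.approx((4 + 7) / 14)


def _fit_with_coefs(coefs: dict) -> LmmFit:
    return LmmFit(
        outcome="daily_steps", scale="steps", fixed_effects={},
        group_coefficients=coefs, net_difference=0.0, net_ci=(0.0, 0.0),
        interaction_pvalue=None, re_intercept_sd=None, re_slope_sd=None,
        resid_sd=None, n_obs=0, n_participants=0, converged=True,
    )


class TestRuninAdjust:
    @pytest.fixture
    def weekly(self):
        return pd.DataFrame({
            "group": ["control"] * 3 + ["intervention"] * 3,
            "week": [1, 2, 3] * 2,
            "mean": [7000.0, 6800.0, 6600.0, 7100.0, 6900.0, 7000.0],
            "n_obs": [70] * 6,
        })

    def test_zero_coefficients_change_nothing(self, weekly):
        out = runin_adjust(weekly, _fit_with_coefs({"control": 0.0, "intervention": 0.0}))
        pd.testing.assert_frame_equal(out, weekly)

    def test_additive_shift_applies_to_runin_week_only(self, weekly):
        out = runin_adjust(weekly, _fit_with_coefs({"control": 0.0, "intervention": 200.0}))
        assert out.loc[(out["group"] == "intervention") & (out["week"] == 1), "mean"].iloc[0] == 7300.0
        unchanged = out[(out["week"] != 1) | (out["group"] == "control")]["mean"]
        original = weekly[(weekly["week"] != 1) | (weekly["group"] == "control")]["mean"]
        assert (unchanged.values == original.values).all()

    def test_adjust_then_subtract_is_identity(self, weekly):
        coefs = {"control": -150.0, "intervention": 320.0}
        out = runin_adjust(weekly, _fit_with_coefs(coefs))
        back = out.copy()
        mask = back["week"] == 1
        back.loc[mask, "mean"] = back.loc[mask].apply(
            lambda r: r["mean"] - coefs[r["group"]], axis=1
        )
        pd.testing.assert_frame_equal(back, weekly)

    def test_unknown_arm_rejected(self, weekly):
        with pytest.raises(ValueError):
            runin_adjust(weekly, _fit_with_coefs({"control": 0.0}))


class TestMovingAverage:
    def test_constant_series_is_constant(self):
        out = moving_average([5.0] * 20, 7)
        assert out.shape == (14,)
        assert np.allclose(out, 5.0)

    def test_runin_ramp_averages_to_4500(self):
        out = moving_average([3000, 3500, 4000, 4500, 5000, 5500, 6000], 7)
        assert out.shape == (1,)
        assert out[0] == pytest.approx(31500 / 7) == pytest.approx(4500)

    def test_window_one_is_identity(self):
        x = [1.0, 4.0, 9.0]
        assert np.allclose(moving_average(x, 1), x)

    def test_missing_values_averaged_over_observed_subset(self):
        out = moving_average([1000, None, 3000], 3)
        assert out[0] == pytest.approx(2000)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1.0, 2.0], 7)


class TestFrequentUsers:
    def _ds_with_mask(self, off_days: set[int], days=70):
        h = make_history("P1", days, lambda d: 6000, group=Group.CONTROL,
                         missing_days=off_days)
        h2 = make_history("P2", days, lambda d: 6000, group=Group.INTERVENTION)
        return _dataset([h, h2])

    def test_always_active_is_frequent(self):
        labels = classify_frequent_users(self._ds_with_mask(set()))
        assert labels["P1"] == FREQUENT

    def test_exactly_seven_consecutive_off_days_is_nonfrequent(self):
        labels = classify_frequent_users(self._ds_with_mask(set(range(20, 27))))
        assert labels["P1"] == NONFREQUENT

    def test_repeated_six_day_runs_stay_frequent(self):
        off = set(range(10, 16)) | set(range(30, 36)) | set(range(50, 56))
        labels = classify_frequent_users(self._ds_with_mask(off))
        assert labels["P1"] == FREQUENT

    def test_agrees_with_brute_force_on_random_masks(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            active = list(rng.random(30) > 0.2)
            h = ParticipantHistory("P1", [
                DailyRecord("P1", d + 1, 5000, 4000 if a else None, a,
                            Group.CONTROL if d + 1 > 7 else Group.UNASSIGNED)
                for d, a in enumerate(active)
            ])
            label = classify_frequent_users(_dataset([h]))["P1"]
            expected = NONFREQUENT if brute_force_max_run(active) >= 7 else FREQUENT
            assert label == expected


class TestPerProtocol:
    def test_all_frequent_is_identity(self, small_dataset):
        out = per_protocol_subset(small_dataset)
        assert out.participant_ids == small_dataset.participant_ids

    def test_mixed_cohort_keeps_frequent_only(self):
        freq = [make_history(f"F{i}", 30, lambda d: 6000, group=Group.CONTROL)
                for i in range(4)]
        nonfreq = [make_history(f"N{i}", 30, lambda d: 6000, group=Group.CONTROL,
                                missing_days=set(range(10, 18)))
                   for i in range(2)]
        out = per_protocol_subset(_dataset(freq + nonfreq))
        assert sorted(out.participant_ids) == [f"F{i}" for i in range(4)]

    def test_empty_subset_is_an_error(self):
        hists = [make_history(f"N{i}", 30, lambda d: 6000, group=Group.CONTROL,
                              missing_days=set(range(10, 18)))
                 for i in range(2)]
        with pytest.raises(InsufficientDataError):
            per_protocol_subset(_dataset(hists))


class TestTTest:
    def test_identical_samples(self):
        res = two_sample_ttest([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.mean_difference == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_textbook_example(self):
        res = two_sample_ttest([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.t == pytest.approx(-1.0)
        assert res.df == 8
        assert res.mean_difference == pytest.approx(-1.0)

    def test_zero_variance_equal_means(self):
        res = two_sample_ttest([5.0, 5.0], [5.0, 5.0])
        assert res.t == 0.0 and res.pvalue == 1.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_sample_ttest([1.0], [2.0, 3.0])

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(23)
        reps, n = 2000, 10
        rejections = 0
        for _ in range(reps):
            res = two_sample_ttest(rng.normal(0, 1, n), rng.normal(0, 1, n))
            rejections += res.pvalue < 0.05
        se = math.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps == pytest.approx(0.05, abs=3 * se)


class TestPowerAndSampleSize:
    def test_zero_effect_power_equals_alpha(self):
        spec = PowerSpec(delta=0.0 + 1e-12, sd=2000, alpha=0.05)
        assert power_two_sample(25, spec) == pytest.approx(0.05, abs=1e-6)

    def test_design_point_reaches_eighty_percent(self):
        assert power_two_sample(30, PowerSpec(1500, 2000)) >= 0.80

    def test_matches_monte_carlo_power(self):
        spec = PowerSpec(delta=1000, sd=2000, alpha=0.05)
        n, reps = 15, 20_000
        rng = np.random.default_rng(31)
        x = rng.normal(spec.delta, spec.sd, (reps, n))
        y = rng.normal(0.0, spec.sd, (reps, n))
        sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * 2 / n)
        crit = stats.t.ppf(0.975, 2 * n - 2)
        mc = np.mean(np.abs(t) > crit)
        exact = power_two_sample(n, spec)
        se = math.sqrt(exact * (1 - exact) / reps)
        assert mc == pytest.approx(exact, abs=3 * se)

    def test_exact_design_sample_size(self):
        res = sample_size(PowerSpec(1500, 2000, alpha=0.05, power=0.80))
        assert res.n_per_group == 29

    def test_attrition_inflation_monotone(self):
        r0 = sample_size(PowerSpec(1500, 2000))
        r1 = sample_size(PowerSpec(1500, 2000, attrition=0.1))
        assert r1.n_inflated > r0.n_inflated

    def test_power_target_monotone(self):
        r80 = sample_size(PowerSpec(1500, 2000, power=0.80))
        r90 = sample_size(PowerSpec(1500, 2000, power=0.90))
        assert r90.n_per_group > r80.n_per_group

    def test_power_nondecreasing_in_n_and_delta(self):
        spec = PowerSpec(800, 2000)
        powers = [power_two_sample(n, spec) for n in (5, 10, 20, 40, 80)]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        by_delta = [power_two_sample(20, PowerSpec(d, 2000)) for d in (200, 800, 1600, 2400)]
        assert all(b > a for a, b in zip(by_delta, by_delta[1:]))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(1500, -1)
        with pytest.raises(ValueError):
            PowerSpec(1500, 2000, alpha=1.5)
        with pytest.raises(ValueError):
            power_two_sample(1, PowerSpec(1500, 2000))
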