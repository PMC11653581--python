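import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from patchpk.titration import (
    PatientRecord,
    dichotomize,
    multivariate_aor,
    titration_period,
    univariate_screen,
)


def record(doses, rescues, pid="p1"):
    return PatientRecord(patient_id=pid, daily_dose=doses, daily_rescue_count=rescues)


def brute_force_period(doses, rescues, stability_days=5, rescue_max=3):
    """Independent exhaustive check of every candidate window."""
    n = len(doses)
    for end_day in range(stability_days, n + 1):
        days = range(end_day - stability_days, end_day)  # 0-based
        if all(doses[d] == doses[end_day - stability_days] for d in days) and all(
            rescues[d] <= rescue_max for d in days
        ):
            return end_day
    return None


class TestWindowRule:
    def test_stable_from_day_one_gives_minimum_period(self):
        out = titration_period(record([1] * 8, [0, 1, 2, 3, 0, 1, 0, 2]))
        assert out.titration_period == 5
        assert out.group == "within_5"

    def test_dose_change_between_days_4_and_5(self):
        # windows ending days 5-8 all straddle the day-4/5 dose change;
        # the first constant-dose window is days 5-9
        doses = [1] * 4 + [2] * 12
        out = titration_period(record(doses, [0] * 16))
        assert out.titration_period == 9
        assert out.group == "six_or_more"

    def test_rescue_violation_on_day_3_delays_to_day_8(self):
        # windows ending days 5, 6 and 7 all contain day 3 (rescue 4);
        # the first clean window is days 4-8
        rescues = [0, 0, 4, 0, 0, 0, 0, 0, 0]
        out = titration_period(record([1] * 9, rescues))
        assert out.titration_period == 8

    def test_final_day_rescue_convention_exposed(self):
        rescues = [0, 0, 4, 0, 0, 0, 0, 0, 0]
        out = titration_period(
            record([1] * 9, rescues), rescue_convention="final_day"
        )
        assert out.titration_period == 5

    def test_never_stable_record_is_censored(self):
        doses = [1, 2] * 5  # dose flips every day
        out = titration_period(record(doses, [0] * 10))
        assert out.censored and out.titration_period is None

    def test_record_shorter_than_window_rejected(self):
        rec = record([1] * 5, [0] * 5)
        with pytest.raises(ValueError):
            titration_period(rec, stability_days=6)

    def test_agrees_with_brute_force_on_random_records(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(5, 30))
            doses = list(rng.choice([0.5, 1.0, 2.0, 4.0], size=n))
            # encourage runs of constant dose
            for i in range(1, n):
                if rng.random() < 0.7:
                    doses[i] = doses[i - 1]
            rescues = list(rng.poisson(2.0, size=n))
            out = titration_period(record(doses, rescues))
            expected = brute_force_period(doses, rescues)
            assert out.titration_period == expected


class TestDichotomize:
    def test_cutoff_and_censored_handling(self):
        outs = [
            titration_period(record([1] * 10, [0] * 10)),  # period 5
            titration_period(record([1] * 4 + [2] * 7, [0] * 11)),  # period 9
            titration_period(record([1, 2] * 5, [0] * 10)),  # censored
        ]
        y, n_censored = dichotomize(outs)
        assert list(y) == [0, 1]
        assert n_censored == 1

    @pytest.mark.parametrize("period, expected", [(5, 0), (6, 1), (39, 1)])
    def test_boundary(self, period, expected):
        # rescue overuse every 5th day counting back from day period-5
        # blocks every earlier window (period 39 is the observed maximum)
        n = period + 3
        rescues = [0] * n
        day = period - 5
        while day >= 1:
            rescues[day - 1] = 4
            day -= 5
        out = titration_period(record([1] * n, rescues))
        assert out.titration_period == period
        y, _ = dichotomize([out])
        assert y[0] == expected


def expand_2x2(a, b, c, d):
    """Rows of a 2x2 exposure-outcome table as unit records."""
    x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=int)
    return pd.DataFrame({"patient_id": range(len(x)), "exposed": x}), y


class TestUnivariateScreen:
    @pytest.mark.parametrize(
        "table", [(13, 53, 113, 208), (4, 1, 122, 257), (7, 3, 119, 258), (20, 30, 40, 50)]
    )
    def test_single_binary_predictor_equals_cross_ratio(self, table):
        a, b, c, d = table
        cohort, y = expand_2x2(a, b, c, d)
        results, _ = univariate_screen(cohort, y, factors=["exposed"], alpha_screen=0.1)
        assert results[0].odds_ratio == pytest.approx(a * d / (b * c), rel=1e-8)

    def test_null_predictor_gives_unit_odds_ratio(self):
        rng = np.random.default_rng(11)
        n = 4000
        cohort = pd.DataFrame(
            {"patient_id": range(n), "noise": rng.random(n)}
        )
        y = rng.integers(0, 2, size=n)
        results, selected = univariate_screen(cohort, y, factors=["noise"])
        assert results[0].odds_ratio == pytest.approx(1.0, abs=0.2)
        assert "noise" not in selected or results[0].p_value >= 0.05

    def test_null_p_values_roughly_uniform_over_replicates(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(60):
            n = 400
            cohort = pd.DataFrame({"patient_id": range(n), "x": rng.random(n)})
            y = rng.integers(0, 2, size=n)
            results, _ = univariate_screen(cohort, y, factors=["x"])
            pvals.append(results[0].p_value)
        pvals = np.asarray(pvals)
        assert 0.35 < pvals.mean() < 0.65
        assert np.mean(pvals < 0.1) < 0.3

    def test_perfect_separation_is_flagged(self):
        # every exposed subject has the outcome: no finite MLE
        cohort, y = expand_2x2(8, 0, 50, 60)
        results, selected = univariate_screen(cohort, y, factors=["exposed"])
        assert results[0].flagged
        assert "exposed" not in selected

    def test_zero_variance_factor_skipped_with_note(self):
        rng = np.random.default_rng(3)
        n = 50
        cohort = pd.DataFrame({"patient_id": range(n), "flat": np.zeros(n)})
        results, selected = univariate_screen(cohort, rng.integers(0, 2, n), factors=["flat"])
        assert results[0].flagged and "zero variance" in results[0].note
        assert selected == []

    def test_missing_values_fit_on_complete_cases(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.4).astype(int)
        x[:30] = np.nan
        cohort = pd.DataFrame({"patient_id": range(n), "albumin": x})
        results, _ = univariate_screen(cohort, y, factors=["albumin"])
        assert results[0].n == n - 30


class TestMultivariateAOR:
    def test_single_factor_equals_univariate_fit(self):
        cohort, y = expand_2x2(13, 53, 113, 208)
        uni, _ = univariate_screen(cohort, y, factors=["exposed"])
        multi = multivariate_aor(cohort, y, ["exposed"])
        assert multi[0].odds_ratio == pytest.approx(uni[0].odds_ratio, rel=1e-10)
        assert multi[0].p_value == pytest.approx(uni[0].p_value, rel=1e-8)

    def test_recovers_known_generating_odds_ratios(self):
        # two independent binary covariates with ORs 2.0 and 0.5 at n=5000
        rng = np.random.default_rng(123)
        n = 5000
        x1 = (rng.random(n) < 0.3).astype(float)
        x2 = (rng.random(n) < 0.4).astype(float)
        lp = -0.5 + math.log(2.0) * x1 + math.log(0.5) * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        cohort = pd.DataFrame({"patient_id": range(n), "x1": x1, "x2": x2})
        res = {r.factor: r for r in multivariate_aor(cohort, y, ["x1", "x2"])}
        assert res["x1"].odds_ratio == pytest.approx(2.0, rel=0.10)
        assert res["x2"].odds_ratio == pytest.approx(0.5, rel=0.10)

    def test_score_equations_hold_at_reported_optimum(self):
        rng = np.random.default_rng(21)
        n = 600
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * x1 - 0.8 * x2)))).astype(int)
        cohort = pd.DataFrame({"patient_id": range(n), "x1": x1, "x2": x2})
        res = multivariate_aor(cohort, y, ["x1", "x2"])
        beta = np.array([0.0] + [r.coef for r in res])
        # recompute the intercept by refitting only it? simpler: solve the
        # full fit again and take the statsmodels score at its own optimum
        X = sm.add_constant(cohort[["x1", "x2"]].to_numpy())
        fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10)
        assert np.linalg.norm(sm.Logit(y, X).score(fit.params)) < 1e-6
        np.testing.assert_allclose(fit.params[1:], [r.coef for r in res], rtol=1e-8)

    def test_empty_selection_rejected(self):
        cohort, y = expand_2x2(5, 5, 5, 5)
        with pytest.raises(ValueError):
            multivariate_aor(cohort, y, [])


class TestRecordValidation:
    def test_sequence_length_mismatch(self):
        with pytest.raises(ValueError):
            record([1] * 6, [0] * 5)

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            record([1] * 4, [0] * 4)

    def test_nonpositive_dose(self):
        with pytest.raises(ValueError):
            record([1, 1, 0, 1, 1], [0] * 5)
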