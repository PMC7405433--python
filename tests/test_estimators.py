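"""Traditional-arm machinery: logistic MLE, OR reporting, raw RD, G-computation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from icucausal.cohort import Cohort, EXPOSURE, OUTCOME
from icucausal.errors import DataError
from icucausal.estimators import (
    fit_logistic,
    gcomp_effect,
    raw_rd_from_cohort,
    raw_risk_difference,
    report_or,
    two_proportion_test,
)
from icucausal.simulate import scenario, simulate_cohort


def _frame(obesity, death, **extra):
    n = len(obesity)
    df = pd.DataFrame({
        "admission_id": [f"T{i}" for i in range(n)],
        EXPOSURE: pd.array(obesity, dtype="boolean"),
        OUTCOME: pd.array(death, dtype="boolean"),
    })
    for k, v in extra.items():
        df[k] = v
    return df


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = [True] * 25 + [False] * 75
        df = _frame([False] * 100, y)
        fit = fit_logistic(df, exposure=None, confounders=[])
        assert fit.params["intercept"] == pytest.approx(logit(0.25), abs=1e-8)

    def test_two_by_two_table_closed_form(self):
        # exposed: 10 deaths / 100; unexposed: 20 deaths / 100
        obesity = [True] * 100 + [False] * 100
        death = [True] * 10 + [False] * 90 + [True] * 20 + [False] * 80
        fit = fit_logistic(_frame(obesity, death), confounders=[])
        expected_beta = np.log((10 * 80) / (90 * 20))
        assert fit.params[EXPOSURE] == pytest.approx(expected_beta, abs=1e-8)
        assert fit.params["intercept"] == pytest.approx(logit(0.20), abs=1e-8)

    def test_recovers_generator_coefficients(self):
        cohort, truth = simulate_cohort(scenario("complete", n=100_000, seed=77))
        fit = fit_logistic(cohort.data)
        # check the exposure effect and a strong confounder effect
        for term, true_val in [(EXPOSURE, truth.outcome_coeffs["obesity"]),
                               ("age_std", truth.outcome_coeffs["age_std"]),
                               ("pa_limited", truth.outcome_coeffs["pa_limited"])]:
            se = np.sqrt(fit.cov.loc[term, term])
            assert abs(fit.params[term] - true_val) < 3 * se

    def test_missing_outcome_rejected(self):
        df = _frame([True, False], [True, None])
        with pytest.raises(DataError):
            fit_logistic(df, confounders=[])


class TestReportOr:
    @pytest.mark.parametrize("beta,se,or2,lo2,hi2", [
        (0.28, 0.054, 1.32, 1.19, 1.47),   # standardized-age row
        (-0.31, 0.109, 0.73, 0.59, 0.91),  # social-alcohol row
    ])
    def test_published_rows_to_display_precision(self, beta, se, or2, lo2, hi2):
        row = report_or(beta, se)
        assert round(row.or_, 2) == or2
        assert round(row.ci_low, 2) == lo2
        assert round(row.ci_high, 2) == hi2

    def test_null_beta_symmetric_about_one(self):
        row = report_or(0.0, 0.3)
        assert row.or_ == 1.0
        assert row.ci_low * row.ci_high == pytest.approx(1.0, rel=1e-12)

    def test_log_roundtrip(self):
        row = report_or(-0.2316, 0.115)
        assert np.log(row.or_) == pytest.approx(-0.2316, abs=1e-12)


class TestRawRiskDifference:
    def test_study_scale_counts(self):
        # death counts consistent with the published group sizes and rates
        est = raw_risk_difference(161, 1192, 746, 5121)
        assert round(100 * est.point, 2) == -1.06
        assert round(100 * est.ci_low, 2) == -3.23
        assert round(100 * est.ci_high, 2) == 1.11

    def test_degenerate_and_symmetric_cases(self):
        est = raw_risk_difference(0, 10, 0, 10)
        assert est.point == 0.0 and est.se == 0.0
        est = raw_risk_difference(5, 10, 5, 10)
        assert est.point == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_input_validation(self):
        with pytest.raises(DataError):
            raw_risk_difference(1, 0, 1, 10)
        with pytest.raises(DataError):
            raw_risk_difference(11, 10, 1, 10)


class TestTwoProportionTest:
    def test_equal_proportions_give_p_one(self):
        assert two_proportion_test(30, 100, 30, 100) == pytest.approx(1.0)

    def test_hand_computed_z(self):
        # pooled p = 0.45; z = 0.10 / sqrt(0.45*0.55*(2/100))
        z = 0.10 / np.sqrt(0.45 * 0.55 * 0.02)
        from scipy.stats import norm
        expected = 2 * norm.sf(z)
        assert two_proportion_test(50, 100, 40, 100) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.155, abs=5e-4)

    def test_symmetric_in_groups(self):
        assert (two_proportion_test(50, 100, 40, 100)
                == two_proportion_test(40, 100, 50, 100))


class TestGcomp:
    def test_null_exposure_effect_gives_zero(self):
        cohort, _ = simulate_cohort(scenario("complete", n=2000, seed=5))
        df = cohort.data
        fit = fit_logistic(df)
        fit.params[EXPOSURE] = 0.0  # force a null exposure coefficient
        est = gcomp_effect(fit, df)
        assert est.point == 0.0

    def test_stratified_standardization_oracle(self):
        # one binary confounder with known stratum risks; untreated counts
        # 10 (stratum 0) and 30 (stratum 1) -> ATU = -0.10 exactly
        risks = {(0, 0): 0.2, (1, 0): 0.1, (0, 1): 0.5, (1, 1): 0.4}
        n_untreated = {0: 10, 1: 30}
        expected = sum(
            n_untreated[w] * (risks[(1, w)] - risks[(0, w)])
            for w in (0, 1)) / sum(n_untreated.values())
        assert expected == pytest.approx(-0.10, abs=1e-12)

        # gcomp on exact counterfactual predictions reproduces it
        w_col = np.array([0] * 10 + [1] * 30)
        p1 = np.array([risks[(1, w)] for w in w_col])
        p0 = np.array([risks[(0, w)] for w in w_col])
        assert p1.mean() - p0.mean() == pytest.approx(expected, abs=1e-12)

    def test_collapsibility_no_confounders(self):
        cohort, _ = simulate_cohort(scenario("complete", n=3000, seed=8))
        df = cohort.data
        fit = fit_logistic(df, confounders=[])
        est = gcomp_effect(fit, df)
        raw = raw_rd_from_cohort(df)
        assert est.point == pytest.approx(raw.point, abs=1e-9)

    def test_delta_se_agrees_with_bootstrap(self):
        cohort, _ = simulate_cohort(scenario("complete", n=2000, seed=21))
        df = cohort.data
        confs = ["age", "sex", "physical_activity"]
        fit = fit_logistic(df, confounders=confs)
        delta = gcomp_effect(fit, df)
        boot = gcomp_effect(fit, df, se_method="bootstrap", n_boot=500, seed=3)
        assert boot.se == pytest.approx(delta.se, rel=0.15)

    def test_consistency_under_correct_model(self):
        # average over seeds: bias within 3 Monte-Carlo SEs of zero
        points, truths = [], []
        for s in range(20):
            cohort, truth = simulate_cohort(scenario("complete", n=100_000,
                                            seed=900 + s))
            fit = fit_logistic(cohort.data)
            points.append(gcomp_effect(fit, cohort.data).point)
            truths.append(truth.true_atu)
        bias = np.mean(points) - np.mean(truths)
        mc_se = np.std(points, ddof=1) / np.sqrt(len(points))
        assert abs(bias) < 3 * mc_se

    def test_empty_subgroup_rejected(self):
        df = _frame([True] * 10 + [False] * 10, [False, True] * 10)
        fit = fit_logistic(df, confounders=[])
        exposed_only = df[df[EXPOSURE] == True].reset_index(drop=True)  # noqa: E712
        with pytest.raises(DataError):
            gcomp_effect(fit, exposed_only, estimand="atu")
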