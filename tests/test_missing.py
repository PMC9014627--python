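"""Missing-data methods: MI by arm, Rubin's rules, IPMW, covariate fixes."""

import numpy as np
import pandas as pd
import pytest

import trialadjust as ta
from trialadjust.data import ARM, OUTCOME
from trialadjust.missing import missing_indicator_warning


def _make_result(est, se, measure="risk_difference"):
    return ta.AdjustmentResult(
        estimate_summary_scale=est,
        estimate_estimation_scale=est,
        se_estimation_scale=se,
        ci=(est - 1.96 * se, est + 1.96 * se),
        z_statistic=est / se,
        p_value=0.5,
        method="standardisation",
        estimand=ta.EstimandSpec(measure),
        n_used=100,
    )


class TestRubin:
    def test_hand_computed_example(self):
        results = [_make_result(e, 0.1) for e in (0.1, 0.2, 0.3)]
        combined = ta.rubin_combine(results)
        assert combined.estimate_estimation_scale == pytest.approx(0.2)
        assert combined.se_estimation_scale**2 == pytest.approx(
            0.01 + (1 + 1 / 3) * 0.01
        )

    def test_identical_results_collapse_to_within_variance(self):
        results = [_make_result(0.15, 0.05)] * 5
        combined = ta.rubin_combine(results)
        assert combined.estimate_estimation_scale == pytest.approx(0.15)
        assert combined.se_estimation_scale == pytest.approx(0.05)

    def test_total_variance_at_least_within(self):
        results = [_make_result(e, 0.1) for e in (0.05, 0.1, 0.4)]
        combined = ta.rubin_combine(results)
        assert combined.se_estimation_scale >= 0.1

    def test_mixed_estimands_refused(self):
        with pytest.raises(ta.TrialAdjustError):
            ta.rubin_combine(
                [_make_result(0.1, 0.1), _make_result(0.1, 0.1, "risk_ratio")]
            )

    def test_summary_scale_combination_flagged(self):
        results = [_make_result(np.log(r), 0.1, "risk_ratio") for r in (0.7, 0.8)]
        for r in results:
            r.estimate_summary_scale = float(np.exp(r.estimate_estimation_scale))
        est = ta.rubin_combine(results, scale="estimation")
        summ = ta.rubin_combine(results, scale="summary")
        assert est.estimate_summary_scale != pytest.approx(summ.estimate_summary_scale)
        assert any("summary scale" in n for n in summ.notes)


class TestMIByArm:
    def test_no_missing_outcomes_gives_identical_copies(self, table2_data):
        imps = ta.mi_by_arm(table2_data, m=3, seed=1)
        for d in imps.datasets:
            pd.testing.assert_frame_equal(d.frame, table2_data.frame)

    def test_observed_values_identical_across_imputations(self):
        miss = ta.appendix_missingness_dataset()
        imps = ta.mi_by_arm(miss, m=3, seed=5)
        obs = miss.outcome_observed()
        for d in imps.datasets:
            assert not pd.isna(d.frame[OUTCOME]).any()
            assert np.array_equal(
                d.frame.loc[obs, OUTCOME].to_numpy(), miss.outcome[obs]
            )

    def test_mnar_shift_is_monotone(self):
        miss = ta.appendix_missingness_dataset()
        mar = ta.mi_by_arm(miss, m=5, seed=3)
        down = ta.mi_by_arm(miss, m=5, seed=3, shift=ta.MNARShift(-3.0, -3.0))
        holes = ~miss.outcome_observed()
        rate_mar = np.mean([d.frame.loc[holes, OUTCOME].mean() for d in mar.datasets])
        rate_down = np.mean([d.frame.loc[holes, OUTCOME].mean() for d in down.datasets])
        assert rate_down < rate_mar

    def test_arm_without_observed_outcomes_cannot_impute(self):
        frame = pd.DataFrame(
            {ARM: [0] * 10 + [1] * 10,
             OUTCOME: [0.0, 1.0] * 5 + [np.nan] * 10}
        )
        data = ta.TrialDataset(frame, {}, ta.RandomisationDesign())
        with pytest.raises(ta.TrialAdjustError):
            ta.mi_by_arm(data, m=2, seed=0)

    def test_reproducible_under_seed(self):
        miss = ta.appendix_missingness_dataset()
        a = ta.mi_by_arm(miss, m=2, seed=42)
        b = ta.mi_by_arm(miss, m=2, seed=42)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da.frame, db.frame)


class TestIPMW:
    def test_uniform_missingness_gives_flat_weights(self, rng):
        n = 400
        y = rng.binomial(1, 0.4, n).astype(float)
        y[:80] = np.nan  # 20% missing, independent of everything
        frame = pd.DataFrame({ARM: np.tile([0, 1], n // 2), OUTCOME: y})
        data = ta.TrialDataset(frame, {}, ta.RandomisationDesign())
        w = ta.ipmw_weights(data)
        observed = data.outcome_observed()
        # by-arm intercept-only model: weights equal the inverse observed
        # fraction within each arm
        for arm in (0, 1):
            sel = observed & (data.arm == arm)
            expected = (data.arm == arm).sum() / sel.sum()
            assert np.allclose(w.weights[sel], expected)

    def test_appendix_missingness_weights(self):
        miss = ta.appendix_missingness_dataset()
        w = ta.ipmw_weights(miss)
        observed = miss.outcome_observed()
        x = miss.frame["x"].to_numpy()
        assert np.allclose(w.weights[observed & (x == 0)], 2.0)
        assert np.allclose(w.weights[observed & (x == 1)], 1.0)

    def test_iptw_plus_ipmw_recovers_all_randomised_rd(self):
        miss = ta.appendix_missingness_dataset()
        combined = ta.combine_weights(
            ta.fit_treatment_weights(miss), ta.ipmw_weights(miss)
        )
        res = ta.iptw_estimate(miss, combined, ta.EstimandSpec("risk_difference"))
        assert res.estimate_summary_scale == pytest.approx(-0.056, abs=1e-9)


class TestCovariateMissingness:
    def _data_with_missing_x(self):
        frame = pd.DataFrame(
            {
                ARM: [0, 1] * 10,
                OUTCOME: [0.0, 1.0, 1.0, 0.0] * 5,
                "x": [0.0, 1.0, np.nan, 1.0] * 5,
            }
        )
        return ta.TrialDataset(
            frame, {"x": ta.CovariateSpec("continuous")}, ta.RandomisationDesign()
        )

    def test_mean_impute_uses_across_arm_mean(self):
        data = self._data_with_missing_x()
        observed_mean = data.frame["x"].mean()
        imputed = ta.covariate_mean_impute(data)
        filled = imputed.frame.loc[data.frame["x"].isna(), "x"]
        assert np.allclose(filled, observed_mean)
        # outcome untouched, original unchanged
        assert data.frame["x"].isna().sum() == 5
        assert np.array_equal(imputed.outcome, data.outcome)

    def test_mean_impute_identity_when_complete(self, table2_data):
        out = ta.covariate_mean_impute(table2_data)
        pd.testing.assert_frame_equal(out.frame, table2_data.frame)

    def test_missing_indicator_construction(self):
        data = self._data_with_missing_x()
        out = ta.covariate_missing_indicator(data)
        assert "x_missing" in out.frame.columns
        assert out.frame["x_missing"].sum() == 5
        assert not out.frame["x"].isna().any()

    def test_indicator_name_collision(self):
        data = self._data_with_missing_x()
        data.frame["x_missing"] = 0.0
        with pytest.raises(ta.TrialAdjustError):
            ta.covariate_missing_indicator(data)

    def test_unsuitable_for_conditional_or(self):
        assert missing_indicator_warning(ta.EstimandSpec("conditional_odds_ratio"))
        assert missing_indicator_warning(ta.EstimandSpec("risk_difference")) is None

    def test_entirely_missing_covariate_rejected(self):
        data = self._data_with_missing_x()
        data.frame["x"] = np.nan
        with pytest.raises(ta.TrialAdjustError):
            ta.covariate_mean_impute(data)


class TestCompleteCases:
    def test_appendix_complete_cases_match_fixture(self, appendix):
        miss = ta.appendix_missingness_dataset()
        cc = ta.complete_cases(miss)
        counts = ta.collapse(cc, "x")
        assert np.array_equal(counts.events, appendix.complete_case.events)
        assert np.array_equal(counts.nonevents, appendix.complete_case.nonevents)

    def test_identity_without_missingness(self, table2_data):
        out = ta.complete_cases(table2_data)
        pd.testing.assert_frame_equal(out.frame, table2_data.frame)

    def test_cc_risk_ratio_differs_from_all_randomised(self, appendix_cc):
        res = ta.standardise(appendix_cc, ta.StandardisationSpec("risk_ratio"))
        assert res.estimate_summary_scale == pytest.approx(0.761, abs=0.005)
        assert abs(res.estimate_summary_scale - 0.748) > 0.005
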