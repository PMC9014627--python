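"""Synthetic trials: randomisation schemes, analytic truth, fixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest

import trialadjust as ta
from trialadjust.data import ARM
from trialadjust.simulate import (
    FixtureError,
    MisspecificationScenario,
    _oracle_cell_risks,
    assign_simple,
    true_estimands,
)


class TestStratifiedBlocks:
    def test_complete_blocks_balance_exactly(self):
        arms = ta.assign_stratified_blocks(["s"] * 8, 4, rng=0)
        assert arms.sum() == 4

    def test_incomplete_final_block_bounded_imbalance(self):
        for seed in range(10):
            arms = ta.assign_stratified_blocks(["s"] * 10, 4, rng=seed)
            assert abs(arms.sum() - 5) <= 2

    def test_two_strata_cross_tab_balanced(self):
        labels = ["a"] * 12 + ["b"] * 8
        arms = ta.assign_stratified_blocks(labels, 4, rng=1)
        labels = np.asarray(labels)
        for s in ("a", "b"):
            assert arms[labels == s].sum() == (labels == s).sum() / 2

    def test_indivisible_block_size_rejected(self):
        with pytest.raises(ta.TrialAdjustError):
            ta.assign_stratified_blocks(["s"] * 8, 5, allocation_ratio=(1, 1))


class TestMinimisation:
    def test_first_participant_is_a_coin_flip(self):
        records = pd.DataFrame({"g": ["m"]})
        draws = {ta.assign_minimisation(records, rng=s)[0] for s in range(20)}
        assert draws == {0, 1}

    def test_deterministic_minimisation_bounds_imbalance(self):
        """prob_favoured = 1 with one binary covariate: across every one of
        the 2^8 covariate orderings, within-level arm counts never differ by
        more than 1 (brute force)."""
        for bits in itertools.product([0, 1], repeat=8):
            records = pd.DataFrame({"g": list(bits)})
            arms = ta.assign_minimisation(records, prob_favoured=1.0, rng=7)
            for level in (0, 1):
                sel = np.asarray(bits) == level
                if sel.any():
                    diff = abs(arms[sel].sum() - (sel.sum() - arms[sel].sum()))
                    assert diff <= 1

    def test_minimisation_tightens_imbalance_vs_simple(self):
        rng = np.random.default_rng(12)
        imb_min, imb_simple = [], []
        for _ in range(150):
            g = rng.integers(0, 2, 60)
            records = pd.DataFrame({"g": g})
            a_min = ta.assign_minimisation(records, prob_favoured=0.8,
                                           rng=rng.integers(2**31))
            a_sim = assign_simple(60, rng=rng.integers(2**31))
            for arms, store in ((a_min, imb_min), (a_sim, imb_simple)):
                sel = g == 1
                store.append(arms[sel].sum() - sel.sum() / 2)
        assert np.var(imb_min) < np.var(imb_simple)

    def test_continuous_balancing_covariate_rejected(self):
        with pytest.raises(ta.TrialAdjustError):
            ta.assign_minimisation(pd.DataFrame({"age": [1.5, 2.5]}))


class TestGenerateTrial:
    covs = [ta.CovariateDist("x", "categorical", (0, 1), (0.5, 0.5))]

    def test_null_effect_gives_null_truth(self):
        outcome = ta.OutcomeModelSpec("binomial", "logit", -0.5, 0.0, {"x": 1.0})
        truth = true_estimands(self.covs, outcome)
        assert truth.risk_difference == pytest.approx(0.0, abs=1e-12)
        assert truth.log_risk_ratio == pytest.approx(0.0, abs=1e-12)
        assert truth.marginal_log_odds_ratio == pytest.approx(0.0, abs=1e-12)

    def test_non_collapsibility_direction(self):
        outcome = ta.OutcomeModelSpec("binomial", "logit", -1.0, 0.8, {"x": 2.0})
        truth = true_estimands(self.covs, outcome)
        assert abs(truth.marginal_log_odds_ratio) < abs(
            truth.conditional_log_odds_ratio
        )

    def test_gaussian_marginal_equals_conditional(self):
        outcome = ta.OutcomeModelSpec(
            "gaussian", "identity", 0.3, 0.7, {"x": 1.0}, residual_sd=1.0
        )
        truth = true_estimands(self.covs, outcome)
        assert truth.mean_difference == pytest.approx(0.7, abs=1e-12)

    def test_bitwise_reproducible(self):
        outcome = ta.OutcomeModelSpec("binomial", "logit", -0.5, 0.5, {"x": 1.0})
        a, _ = ta.generate_trial(100, ta.RandomisationDesign(), self.covs, outcome, seed=3)
        b, _ = ta.generate_trial(100, ta.RandomisationDesign(), self.covs, outcome, seed=3)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_truth_matches_large_monte_carlo(self):
        outcome = ta.OutcomeModelSpec(
            "binomial", "logit", -0.8, 0.6, {"x": 1.5},
            effect_modification={"x": 0.4},
        )
        truth = true_estimands(self.covs, outcome)
        n = 400_000
        data, _ = ta.generate_trial(n, ta.RandomisationDesign(), self.covs,
                                    outcome, seed=99)
        y, z = data.outcome, data.arm
        for arm, target in ((1, truth.mean1), (0, truth.mean0)):
            est = y[z == arm].mean()
            mc_se = np.sqrt(target * (1 - target) / (z == arm).sum())
            assert abs(est - target) < 3 * mc_se

    def test_invalid_probability_rejected(self):
        outcome = ta.OutcomeModelSpec("binomial", "identity", 0.9, 0.3, {"x": 0.2})
        with pytest.raises(ta.TrialAdjustError):
            true_estimands(self.covs, outcome)

    def test_missingness_mechanisms(self):
        outcome = ta.OutcomeModelSpec("binomial", "logit", -0.5, 0.5, {"x": 1.0})
        miss = ta.MissingnessSpec("covariate_dependent", "x", {0: 0.5, 1: 0.0})
        data, _ = ta.generate_trial(4000, ta.RandomisationDesign(), self.covs,
                                    outcome, miss, seed=21)
        observed = data.outcome_observed()
        x = data.frame["x"].to_numpy()
        assert observed[x == 1].all()
        assert abs((~observed[x == 0]).mean() - 0.5) < 0.05

    def test_stratified_design_balances_stratum_arm_table(self):
        outcome = ta.OutcomeModelSpec("binomial", "logit", -0.5, 0.5, {"x": 1.0})
        design = ta.RandomisationDesign(
            "stratified_block", strata_covariates=("x",), block_size=4
        )
        data, _ = ta.generate_trial(200, design, self.covs, outcome, seed=17)
        x = data.frame["x"].to_numpy()
        for level in (0, 1):
            sel = x == level
            assert abs(data.arm[sel].sum() - sel.sum() / 2) <= 2


class TestFigure1:
    def test_centred_interval_kills_lambda(self):
        sc = ta.figure1_experiment(intervals=[(-0.5, 0.5)])[0]
        assert abs(sc.lambda_hat) < 1e-8
        assert sc.theta_hat == pytest.approx(1.0, abs=1e-10)

    def test_shifted_intervals_partially_adjust(self):
        scs = ta.figure1_experiment(intervals=[(0.0, 1.0), (0.5, 1.5)])
        for sc in scs:
            assert sc.lambda_hat > 0
        assert scs[1].lambda_hat > scs[0].lambda_hat

    def test_adjustment_never_less_efficient(self):
        for sc in ta.figure1_experiment():
            assert sc.se_adjusted <= sc.se_unadjusted + 1e-12

    def test_stochastic_variant_reproducible(self):
        a = ta.figure1_experiment(stochastic=True, seed=5)
        b = ta.figure1_experiment(stochastic=True, seed=5)
        assert a == b
        assert isinstance(a[0], MisspecificationScenario)


class TestFixtures:
    def test_table2_shape(self, table2_counts):
        assert np.array_equal(table2_counts.events, [[5, 9], [1, 5]])
        within_or = (
            table2_counts.events[:, 1] / table2_counts.nonevents[:, 1]
        ) / (table2_counts.events[:, 0] / table2_counts.nonevents[:, 0])
        assert within_or == pytest.approx([9.0, 9.0])
        assert table2_counts.marginal_measure("marginal_odds_ratio") == pytest.approx(
            49 / 9
        )

    def test_appendix_fixture_satisfies_reconstruction_oracle(self, appendix):
        oracle = _oracle_cell_risks()
        assert np.max(np.abs(appendix.cell_risks - oracle)) < 0.0035
        # the published approximate risks
        assert appendix.cell_risks[0, 0] == pytest.approx(0.086, abs=0.001)
        assert appendix.cell_risks[1, 0] == pytest.approx(0.054, abs=0.001)
        assert appendix.cell_risks[0, 1] == pytest.approx(0.358, abs=0.001)
        assert appendix.cell_risks[1, 1] == pytest.approx(0.278, abs=0.001)

    def test_corrupted_fixture_fails_oracle_check(self, monkeypatch):
        import trialadjust.simulate as sim

        bad = {**sim._NOTIONAL_SUMMARIES, "rd_all": -0.2}
        monkeypatch.setattr(sim, "_NOTIONAL_SUMMARIES", bad)
        with pytest.raises(FixtureError):
            sim.fixture_appendix_table5()

    def test_appendix_counts(self, appendix):
        assert appendix.full.totals.sum() == 2000
        assert (appendix.full.totals == 500).all()
        assert appendix.complete_case.totals.sum() == 3000
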