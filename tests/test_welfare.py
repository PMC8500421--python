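import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribeval import (
    ContractTerms,
    WelfareParams,
    certainty_equivalent,
    classify_payouts,
    decompose_ib,
    evaluate_contract,
    expected_utility,
    ib_hat,
    insurance_benefit,
    rho_sweep,
    rib,
    shadow_value,
    utility,
)
from ribeval.contracts import indemnity, price_contract


class TestUtility:
    def test_crra_at_rho_two(self):
        assert utility(1000.0, 2.0) == pytest.approx(-0.001)

    def test_risk_neutral(self):
        assert utility(7.5, 0.0) == pytest.approx(7.5)

    def test_log_branch(self):
        assert utility(1.0, 1.0) == 0.0
        assert utility(np.e, 1.0) == pytest.approx(1.0)

    def test_nonpositive_wealth_rejected(self):
        with pytest.raises(ValueError):
            utility(-1.0, 2.0)


class TestShadowValue:
    def test_unit_wealth(self):
        for rho in (0.0, 1.0, 2.0, 3.0):
            assert shadow_value(1.0, rho) == pytest.approx(1.0)

    def test_inverse_square_at_rho_two(self):
        assert shadow_value(0.5, 2.0) / shadow_value(1.0, 2.0) == pytest.approx(4.0)

    def test_risk_neutral_constant(self):
        np.testing.assert_allclose(shadow_value(np.array([0.2, 1, 5]), 0.0), 1.0)

    def test_decreasing_in_wealth(self):
        k = np.linspace(0.1, 2, 30)
        assert np.all(np.diff(shadow_value(k, 2.0)) < 0)


class TestExpectedUtilityAndCE:
    def test_two_state_example(self):
        assert expected_utility([1.0, 0.5], 2.0, [0.5, 0.5]) == pytest.approx(-1.5)

    def test_single_state(self):
        assert expected_utility([0.8], 2.0) == pytest.approx(utility(0.8, 2.0))

    def test_risk_neutral_is_expected_wealth(self, rng):
        k = rng.uniform(0.2, 1.5, 20)
        assert expected_utility(k, 0.0) == pytest.approx(k.mean())

    def test_ce_example(self):
        assert certainty_equivalent(-1.5, 2.0) == pytest.approx(2.0 / 3.0)

    def test_ce_inverts_utility(self):
        for rho in (0.0, 0.5, 1.0, 2.0, 3.0):
            k = 0.83
            assert certainty_equivalent(utility(k, rho), rho) == pytest.approx(
                k, abs=1e-10
            )

    def test_jensen_ce_below_expected_wealth(self, rng):
        k = rng.uniform(0.3, 1.5, 50)
        for rho in (0.5, 1.0, 2.0):
            ce = certainty_equivalent(expected_utility(k, rho), rho)
            assert ce <= k.mean()
        assert certainty_equivalent(
            expected_utility(k, 0.0), 0.0
        ) == pytest.approx(k.mean())

    @given(rho=st.floats(0.0, 3.0), shift=st.floats(-0.4, 0.4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_ce_monotone_in_eu(self, rho, shift):
        k = np.array([0.5, 0.8, 1.0, 1.2])
        eu = expected_utility(k, rho)
        eu2 = expected_utility(k + 0.5 + abs(shift), rho)
        ce, ce2 = certainty_equivalent(eu, rho), certainty_equivalent(eu2, rho)
        assert ce2 >= ce


class TestBenefitAndRIB:
    def test_identical_contract_zero_benefit(self):
        assert insurance_benefit(-1.5, -1.5) == 0.0
        assert ib_hat(0.66, 0.66) == 0.0

    def test_rib_bounds_and_errors(self):
        assert rib(0.5, 1.0) == 0.5
        assert rib(0.0, 1.0) == 0.0
        assert rib(-0.2, 1.0) == -0.2
        with pytest.raises(ValueError, match="undefined"):
            rib(0.5, 0.0)

    def test_risk_neutral_fair_pricing_is_wealth_neutral(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        terms = ContractTerms(markup=0.0)
        pay = indemnity(m, terms)
        pc = price_contract(pay, terms)
        k_n = 1.0 - m
        k_p = k_n + pay - pc.premium
        ib = insurance_benefit(
            expected_utility(k_p, 0.0), expected_utility(k_n, 0.0)
        )
        assert abs(ib) < 1e-12

    def test_perfect_contract_positive_benefit(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        rep = evaluate_contract(m, m)
        assert rep.ib_p > 0
        assert rep.rib == 1.0

    def test_anticorrelated_index_negative_rib(self, default_panel):
        # an index that pays in exactly the wrong seasons
        m = default_panel["mortality"].to_numpy()
        pred = np.clip(m.max() + m.min() - m, 0, 1)  # mirror image
        rep = evaluate_contract(m, pred)
        assert rep.rib < 0


class TestDecomposition:
    def test_zero_transfer_contract(self):
        dec = decompose_ib(np.zeros(10), np.full(10, 0.9), 2.0)
        assert dec.attrs["total"] == 0.0
        assert dec.attrs["exact_ib"] == pytest.approx(0.0)

    def test_single_state_product(self):
        dec = decompose_ib([0.01], [0.5], 2.0)
        # lambda(0.5) = 4 at rho 2; contribution = 0.01 * 4 * 1
        assert dec.attrs["total"] == pytest.approx(0.04)

    def test_small_transfer_accuracy(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        terms = ContractTerms()
        pay = indemnity(m, terms)
        pc = price_contract(pay, terms)
        k_n = 1.0 - m
        d = 0.01 * (pay - pc.premium)
        dec = decompose_ib(d, k_n, 2.0)
        rel = dec.attrs["approx_error"] / abs(dec.attrs["exact_ib"])
        assert rel < 0.05

    def test_error_order_two_in_scale(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        terms = ContractTerms()
        pay = indemnity(m, terms)
        pc = price_contract(pay, terms)
        k_n = 1.0 - m
        errs = []
        for s in (0.01, 0.005):
            dec = decompose_ib(s * (pay - pc.premium), k_n, 2.0)
            errs.append(dec.attrs["approx_error"])
        assert errs[1] <= 0.35 * errs[0]


class TestClassification:
    @pytest.mark.parametrize(
        "ip, ij, expected",
        [
            (0.0, 0.0, "TN"),
            (0.0, 0.08, "FP"),
            (0.25, 0.05, "FN_intermediate"),  # shortfall 0.20 of insured value
            (0.40, 0.05, "FN_severe"),
            (0.25, 0.20, "FN_small"),
            (0.25, 0.25, "FN_small"),  # exact payment
            (0.25, 0.30, "FP"),  # overpays
        ],
    )
    def test_classes(self, ip, ij, expected):
        assert classify_payouts([ip], [ij])[0] == expected

    def test_partition_exhaustive_and_exclusive(self, rng):
        ip = np.where(rng.random(500) < 0.5, 0.0, rng.uniform(0, 0.7, 500))
        ij = np.where(rng.random(500) < 0.5, 0.0, rng.uniform(0, 0.7, 500))
        classes = classify_payouts(ip, ij)
        assert not any(c is None for c in classes)
        counts = pd.Series(classes).value_counts()
        assert counts.sum() == 500


class TestEvaluateContract:
    def test_perfect_index_rib_exactly_one(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        rep = evaluate_contract(m, m)
        assert rep.rib == 1.0
        assert rep.class_counts["FP"] == 0
        assert rep.class_counts["FN_severe"] == 0

    def test_constant_prediction_below_trigger(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        rep = evaluate_contract(m, np.full_like(m, 0.1))
        assert rep.afp_j == 0.0
        assert rep.premium_j == 0.0
        assert rep.rib == pytest.approx(0.0, abs=1e-12)

    def test_class_counts_sum_to_n(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        rep = evaluate_contract(m, np.clip(m + 0.05, 0, 1))
        assert sum(rep.class_counts.values()) == rep.n

    def test_currency_scale_invariance(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        pred = np.clip(m * 0.9, 0, 1)
        rep1 = evaluate_contract(m, pred, ContractTerms(unit_value=1.0))
        rep2 = evaluate_contract(m, pred, ContractTerms(unit_value=1000.0))
        assert abs(rep1.rib - rep2.rib) <= 1e-10
        assert rep2.ce_n == pytest.approx(1000.0 * rep1.ce_n, rel=1e-12)

    def test_total_loss_without_floor_raises(self):
        m = np.array([0.0, 1.0, 0.2])
        with pytest.raises(ValueError, match="non-positive wealth"):
            evaluate_contract(m, m, params=WelfareParams(rho=2.0))

    def test_wealth_floor_clips(self):
        m = np.array([0.0, 1.0, 0.2])
        rep = evaluate_contract(
            m, m, params=WelfareParams(rho=2.0, wealth_floor=0.01)
        )
        assert np.isfinite(rep.rib)


class TestRhoSweep:
    def test_perfect_index_rib_one_everywhere(self, default_panel):
        # unloaded contract so perfect insurance is beneficial at every
        # positive risk aversion, keeping RIB defined across the grid
        m = default_panel["mortality"].to_numpy()
        table = rho_sweep(
            m, m, ContractTerms(markup=0.0), rho_grid=[0.5, 1.0, 2.0, 3.0]
        )
        np.testing.assert_allclose(table["rib"], 1.0)

    def test_risk_neutral_markup_is_pure_cost(self, default_panel):
        m = default_panel["mortality"].to_numpy()
        table = rho_sweep(m, m, rho_grid=[0.0])
        assert table["ib_j"].iloc[0] < 0
        assert np.isnan(table["rib"].iloc[0])

    def test_continuity_at_log_utility(self, default_panel):
        # RIB(rho) is smooth through the log-utility branch: the value at
        # rho = 1 matches the average of its neighbours at 1 +/- 1e-3 to
        # second order
        m = default_panel["mortality"].to_numpy()
        pred = np.clip(m + 0.04 * np.sin(np.arange(m.size)), 0, 1)
        table = rho_sweep(m, pred, rho_grid=[1 - 1e-3, 1.0, 1 + 1e-3])
        ribs = table["rib"].to_numpy()
        assert abs(ribs[1] - 0.5 * (ribs[0] + ribs[2])) < 1e-4
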