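"""Economics-engine tests: OPEX composition, DCF identities, MPSP solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batchtea.economics import (EconomicAssumptions, ScenarioInputs,
                                build_cash_flow, compute_opex, compute_upc,
                                irr, labor_factors, npv, scenario_flows,
                                solve_mpsp)


class TestLaborFactors:
    @pytest.mark.parametrize("rate, expected", [
        (41.4, (0.1, 0.2)),   # baseline wage, top tier
        (3.0, (0.9, 0.8)),    # lowest tier
        (12.0, (0.3, 0.3)),   # mid ladder
        (7.0, (0.5, 0.5)),
        (16.0, (0.2, 0.2)),   # interpolated band
        (25.0, (0.1, 0.2)),
    ])
    def test_tier_ladder(self, rate, expected):
        assert labor_factors(rate) == expected

    def test_rejects_non_positive_rate(self):
        with pytest.raises(ValueError):
            labor_factors(0.0)

    def test_factors_non_increasing_in_rate(self):
        rates = np.linspace(0.5, 60.0, 200)
        admin = [labor_factors(r)[0] for r in rates]
        sup = [labor_factors(r)[1] for r in rates]
        assert all(a >= b for a, b in zip(admin, admin[1:]))
        assert all(a >= b for a, b in zip(sup, sup[1:]))


class TestOpex:
    def test_baseline_reproduces_published_cost_sheet(self, baseline_opex):
        opex, _ = baseline_opex
        assert opex.total == pytest.approx(5_776_000, rel=0.01)
        assert opex.raw_materials == pytest.approx(2_143_000, rel=0.01)
        assert opex.facility_dependent == pytest.approx(1_325_000, rel=0.01)
        assert opex.labor_dependent == pytest.approx(1_238_000, rel=0.01)
        assert opex.lab_qc_qa == pytest.approx(186_000, rel=0.01)
        assert opex.waste_treatment == pytest.approx(884_000, rel=0.01)

    def test_category_shares_sum_to_100(self, baseline_opex):
        opex, _ = baseline_opex
        assert sum(opex.shares().values()) == pytest.approx(100.0, abs=0.01)

    def test_raw_material_category_is_linear_in_prices(self, baseline_inputs,
                                                       assumptions, baseline_opex):
        base, flows = baseline_opex
        doubled = ScenarioInputs.from_flat({
            **baseline_inputs.to_flat(),
            **{k: 2 * v for k, v in baseline_inputs.raw_prices.items()},
        })
        opex2 = compute_opex(doubled, flows, assumptions)
        assert opex2.raw_materials == pytest.approx(2 * base.raw_materials)
        assert opex2.labor_dependent == pytest.approx(base.labor_dependent)
        assert opex2.lab_qc_qa == pytest.approx(base.lab_qc_qa)
        assert opex2.waste_treatment == pytest.approx(base.waste_treatment)
        assert opex2.facility_dependent == pytest.approx(base.facility_dependent)

    def test_labor_cost_back_solved_from_published_value(self):
        # 22,996 h x 41.4 USD/h x (1 + 0.1 + 0.2) within 0.1% of 1,238,000
        admin, sup = labor_factors(41.4)
        assert 22_996 * 41.4 * (1 + admin + sup) == pytest.approx(1_238_000, rel=1e-3)

    def test_missing_price_names_the_material(self, baseline_inputs, assumptions,
                                              baseline_opex):
        _, flows = baseline_opex
        crippled = ScenarioInputs(
            raw_prices={k: v for k, v in baseline_inputs.raw_prices.items()
                        if k != "quinaldine_cost"},
            waste_prices=baseline_inputs.waste_prices,
            labor_rate=41.4, inflation=0.04, income_tax=0.4,
            loan_interest=0.09, loan_period=10, annual_operation_time=7920)
        with pytest.raises(KeyError, match="quinaldine"):
            compute_opex(crippled, flows, assumptions)


class TestUpc:
    @pytest.mark.parametrize("opex, production, expected", [
        (5_776_000, 33_000, 175.0),
        (0.0, 33_000, 0.0),
        (1_000_000, 4_000, 250.0),
    ])
    def test_quotient(self, opex, production, expected):
        assert compute_upc(opex, production) == pytest.approx(expected, abs=0.1)

    def test_zero_production_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compute_upc(1.0, 0.0)

    def test_upc_times_production_recovers_opex(self, baseline_opex):
        opex, flows = baseline_opex
        upc = compute_upc(opex.total, flows.annual_production)
        assert upc * flows.annual_production == pytest.approx(opex.total, rel=1e-12)


class TestNpv:
    def test_analytic_root(self):
        assert npv(np.array([-100.0, 110.0]), 0.10) == pytest.approx(0.0, abs=1e-9)

    def test_zero_rate_is_plain_sum(self):
        cf = np.array([-5.0, 2.0, 2.0, 2.0])
        assert npv(cf, 0.0) == pytest.approx(cf.sum())

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=16),
           st.floats(-0.5, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_discounted_sum(self, flows, r):
        flows = np.array(flows)
        expected = sum(cf / (1.0 + r) ** t for t, cf in enumerate(flows))
        scale = max(1.0, abs(expected))
        assert npv(flows, r) == pytest.approx(expected, rel=1e-9, abs=1e-9 * scale)

    def test_rejects_rate_at_or_below_minus_one(self):
        with pytest.raises(ValueError):
            npv(np.array([-1.0, 2.0]), -1.0)

    def test_strictly_decreasing_in_rate_for_investment_profile(self):
        cf = np.array([-100.0, 30.0, 30.0, 30.0, 30.0, 30.0])
        rates = np.linspace(0.0, 0.5, 20)
        vals = [npv(cf, r) for r in rates]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestIrr:
    def test_analytic_case(self):
        assert irr(np.array([-100.0, 110.0])) == pytest.approx(0.10, abs=1e-6)

    def test_all_positive_flows_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            irr(np.array([10.0, 20.0, 30.0]))

    def test_multiple_sign_changes_warn(self):
        with pytest.warns(RuntimeWarning):
            irr(np.array([-100.0, 250.0, -130.0]))


def _baseline_pieces(assumptions):
    inputs = ScenarioInputs.baseline()
    flows = scenario_flows(inputs)
    opex = compute_opex(inputs, flows, assumptions)
    return inputs, flows, opex


class TestCashFlow:
    def test_zero_price_makes_every_operating_year_negative(self, assumptions):
        inputs, flows, opex = _baseline_pieces(assumptions)
        sched = build_cash_flow(inputs, assumptions, opex,
                                flows.annual_production, 0.0)
        n_con = len(assumptions.construction_spend)
        assert (sched.cash_flows[n_con:] < 0).all()
        assert (sched.cash_flows[:n_con] < 0).all()

    def test_hand_oracle_without_tax_loan_inflation(self):
        # 1-year build, 3 operating years, no startup discount: flow is
        # revenue - cash opex exactly
        assumptions = EconomicAssumptions(lifetime=3, construction_spend=(1.0,),
                                          startup_throughput=1.0,
                                          loan_fraction=0.0)
        inputs = ScenarioInputs.from_flat({
            **ScenarioInputs.baseline().to_flat(),
            "income_tax": 0.0, "inflation": 0.0})
        flows = scenario_flows(inputs)
        opex = compute_opex(inputs, flows, assumptions)
        price = 300.0
        sched = build_cash_flow(inputs, assumptions, opex,
                                flows.annual_production, price)
        revenue = flows.annual_production * price
        cash_opex = opex.total - assumptions.annual_depreciation
        expected = np.array([-assumptions.capex_total] + [revenue - cash_opex] * 3)
        np.testing.assert_allclose(sched.cash_flows, expected, rtol=1e-12)

    def test_schedule_detail_is_consistent(self, assumptions):
        inputs, flows, opex = _baseline_pieces(assumptions)
        sched = build_cash_flow(inputs, assumptions, opex,
                                flows.annual_production, 400.0)
        detail = sched.to_frame()
        recomputed = (detail.revenue - detail.opex - detail.interest
                      - detail.principal - detail.tax - detail.capital)
        np.testing.assert_allclose(detail.net_flow, recomputed, rtol=1e-12)
        assert len(sched.cash_flows) == len(assumptions.construction_spend) + assumptions.lifetime


class TestMpsp:
    def test_round_trip_with_irr(self, assumptions):
        inputs, flows, opex = _baseline_pieces(assumptions)
        price = solve_mpsp(inputs, assumptions, opex, flows.annual_production, 0.30)
        sched = build_cash_flow(inputs, assumptions, opex,
                                flows.annual_production, price)
        assert irr(sched) == pytest.approx(0.30, abs=1e-4)

    def test_npv_vanishes_at_target_rate(self, assumptions):
        inputs, flows, opex = _baseline_pieces(assumptions)
        price = solve_mpsp(inputs, assumptions, opex, flows.annual_production, 0.30)
        sched = build_cash_flow(inputs, assumptions, opex,
                                flows.annual_production, price)
        assert npv(sched, 0.30) == pytest.approx(0.0, abs=1e-3 * assumptions.capex_total * 1e-3)

    def test_matches_dense_price_grid_scan(self, assumptions):
        inputs, flows, opex = _baseline_pieces(assumptions)
        price = solve_mpsp(inputs, assumptions, opex, flows.annual_production, 0.30)
        grid = np.arange(np.floor(price) - 2.0, np.ceil(price) + 2.0, 0.01)
        vals = np.array([npv(build_cash_flow(inputs, assumptions, opex,
                                             flows.annual_production, p), 0.30)
                         for p in grid])
        crossing = grid[np.argmax(vals > 0)]
        assert abs(price - crossing) <= 0.01 + 1e-9

    def test_monotone_in_target_rate(self, assumptions):
        inputs, flows, opex = _baseline_pieces(assumptions)
        p30 = solve_mpsp(inputs, assumptions, opex, flows.annual_production, 0.30)
        p35 = solve_mpsp(inputs, assumptions, opex, flows.annual_production, 0.35)
        assert p35 > p30

    def test_monotone_in_opex_and_above_upc(self, assumptions):
        inputs, flows, opex = _baseline_pieces(assumptions)
        upc = compute_upc(opex.total, flows.annual_production)
        price = solve_mpsp(inputs, assumptions, opex, flows.annual_production, 0.30)
        assert price >= upc
        import dataclasses
        richer = dataclasses.replace(opex, raw_materials=opex.raw_materials * 1.5)
        price2 = solve_mpsp(inputs, assumptions, richer, flows.annual_production, 0.30)
        assert price2 > price

    def test_annuity_limit_at_long_horizon(self):
        # no tax, no inflation, no debt, negligible depreciation, 1-year
        # build: at a 200-year horizon the capital charge approaches the
        # perpetuity capex x r, so MPSP -> UPC + capex x r / production
        assumptions = EconomicAssumptions(lifetime=200, construction_spend=(1.0,),
                                          startup_throughput=1.0,
                                          loan_fraction=0.0,
                                          depreciation_period=100_000)
        inputs = ScenarioInputs.from_flat({
            **ScenarioInputs.baseline().to_flat(),
            "income_tax": 0.0, "inflation": 0.0})
        flows = scenario_flows(inputs)
        opex = compute_opex(inputs, flows, assumptions)
        upc = compute_upc(opex.total, flows.annual_production)
        r = 0.10
        price = solve_mpsp(inputs, assumptions, opex, flows.annual_production, r)
        closed_form = upc + assumptions.capex_total * r / flows.annual_production
        assert price == pytest.approx(closed_form, rel=0.02)

    def test_bracket_failure_is_reported(self, assumptions):
        inputs, flows, opex = _baseline_pieces(assumptions)
        with pytest.raises(ValueError, match="bracket"):
            solve_mpsp(inputs, assumptions, opex, flows.annual_production, 0.30,
                       bracket=(0.0, 1.0))
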