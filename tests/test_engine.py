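"""Deterministic rNPV engine: discounting, valuation, add-ons."""

import numpy as np
import pytest
from scipy import integrate

from orphanval.engine import (
    Conventions,
    Timeline,
    apply_prv,
    apply_tax_credit,
    discount_annual_stream,
    discount_uniform_stream,
    rnpv,
)
from orphanval.market import after_tax_cashflow, peak_treated_patients


class TestDiscountUniformStream:
    def test_no_discounting_returns_amount(self):
        assert discount_uniform_stream(123.0, 0.0, 2.5, 0.0) == pytest.approx(123.0)

    def test_closed_form_vs_numerical_integration(self):
        # oracle: integrate 100 (1.13)^-t over [0, 1]
        num, _ = integrate.quad(lambda t: 100 * 1.13 ** (-t), 0.0, 1.0)
        got = discount_uniform_stream(100.0, 0.0, 1.0, 0.13)
        assert got == pytest.approx(num, rel=1e-9)
        assert got == pytest.approx(94.13, abs=0.005)

    @pytest.mark.parametrize("t0,t1", [(1.0, 1.0), (2.0, 1.5)])
    def test_empty_interval_rejected(self, t0, t1):
        with pytest.raises(ValueError):
            discount_uniform_stream(10.0, t0, t1, 0.1)

    def test_nonninteger_interval_vs_integration(self):
        num, _ = integrate.quad(lambda t: 7.0 / 1.3 * 1.08 ** (-t), 1.2, 2.5)
        assert discount_uniform_stream(7.0, 1.2, 2.5, 0.08) == pytest.approx(
            num, rel=1e-9
        )


class TestDiscountAnnualStream:
    def test_single_year_is_end_of_year_flow(self):
        assert discount_annual_stream(113.0, 0.0, 1.0, 0.13) == pytest.approx(100.0)

    def test_integer_span_is_annuity(self):
        got = discount_annual_stream(300.0, 0.0, 3.0, 0.1)
        annuity = sum(100.0 / 1.1**y for y in (1, 2, 3))
        assert got == pytest.approx(annuity)

    def test_fractional_span_splits_at_year_boundary(self):
        # [0.5, 1.5]: half the flow at year-1 discount, half at year-2
        got = discount_annual_stream(10.0, 0.5, 1.5, 0.1)
        assert got == pytest.approx(5.0 / 1.1 + 5.0 / 1.1**2)

    def test_prices_below_uniform_convention(self):
        # discounting every slice from its year end can only lower the PV
        u = discount_uniform_stream(50.0, 2.0, 4.0, 0.13)
        a = discount_annual_stream(50.0, 2.0, 4.0, 0.13)
        assert a < u


class TestRnpv:
    def test_undiscounted_certain_limit(self, base):
        # r -> 0 and PoS -> 1: value equals plain revenue minus uplifted costs
        s = base.model_copy(deep=True)
        for ph in s.plan.phases:
            ph.pos = 1.0
        res = rnpv(s, discount_rate=0.0)
        cm = s.commercial
        peak_cf = after_tax_cashflow(
            peak_treated_patients(cm.adoption), cm.price, cm
        ) / 1e6
        ramp_years = 1 / 3 + 2 / 3 + 12.0  # 14 exclusivity years on the ramp
        expected = ramp_years * peak_cf - 1.4 * (4 + 14 + 35 + 37)
        assert res.rnpv_overall == pytest.approx(expected, rel=1e-9)

    def test_lower_discount_rate_raises_every_value(self, base):
        hi = rnpv(base, discount_rate=0.13)
        lo = rnpv(base, discount_rate=0.11)
        assert lo.rnpv_overall > hi.rnpv_overall
        assert (lo.value_after_phase > hi.value_after_phase).all()

    def test_conditional_values_increase_along_phases(self, base, lower, upper):
        for s in (base, lower, upper):
            v = rnpv(s).value_after_phase
            assert (np.diff(v) > 0).all()

    def test_impossible_first_phase(self, base):
        s = base.model_copy(deep=True)
        s.plan.phases[0].pos = 0.0
        res = rnpv(s)
        only_cost = -res.components["cost_pv_per_phase"][0] * 1.4
        assert res.rnpv_overall == pytest.approx(only_cost)
        assert np.isnan(res.value_after_phase).all()

    def test_uniform_convention_prices_higher(self, base):
        a = rnpv(base).rnpv_overall
        u = rnpv(base, conventions=Conventions(discounting="uniform")).rnpv_overall
        assert u > a

    def test_sampled_timeline_shortens_exclusivity(self, base):
        # 8 development years leave 20 - 8 = 12 revenue years
        tl = Timeline.from_durations([1, 3, 3, 1])
        res = rnpv(base, timeline=tl)
        assert res.components["exclusivity_years"] == pytest.approx(12.0)
        assert res.rnpv_overall < rnpv(base).rnpv_overall

    def test_orphan_floor_binds_for_very_long_development(self, base):
        tl = Timeline.from_durations([4, 4, 4, 3])
        res = rnpv(base, timeline=tl)
        assert res.components["exclusivity_years"] == pytest.approx(7.0)


class TestMonotonicity:
    def sweep(self, scenario, param, values):
        from orphanval.montecarlo import sensitivity_grid

        return [v for _, v in sensitivity_grid(scenario, param, values)]

    def test_increasing_in_price(self, base):
        vals = self.sweep(base, "price", [20_000, 40_000, 60_000])
        assert vals == sorted(vals) and vals[0] < vals[-1]

    @pytest.mark.parametrize("phase", [0, 1, 2, 3])
    def test_increasing_in_pos(self, base, phase):
        vals = self.sweep(base, f"pos:{phase}", [0.3, 0.6, 0.9])
        assert vals == sorted(vals) and vals[0] < vals[-1]

    def test_increasing_in_patent_term(self, base):
        vals = self.sweep(base, "patent_term", [16.0, 20.0, 24.0])
        assert vals == sorted(vals) and vals[0] < vals[-1]

    @pytest.mark.parametrize("phase", [1, 2])
    def test_decreasing_in_cost(self, base, phase):
        vals = self.sweep(base, f"cost:{phase}", [10.0, 30.0, 60.0])
        assert vals == sorted(vals, reverse=True) and vals[0] > vals[-1]

    def test_decreasing_in_discount_rate(self, base):
        vals = self.sweep(base, "discount_rate", [0.08, 0.11, 0.13, 0.16])
        assert vals == sorted(vals, reverse=True)


def test_cashflow_ledger_sums_to_rnpv(base):
    from orphanval.engine import cashflow_ledger

    s = base.model_copy(deep=True)
    s.flags.include_tax_credit = True
    s.flags.include_prv = True
    df = cashflow_ledger(s)
    assert df["pv_contribution"].sum() == pytest.approx(rnpv(s).rnpv_overall)
    assert (df["element"].str.startswith("cost:")).sum() == 4
    assert "tax_credit" in set(df["element"]) and "prv" in set(df["element"])


class TestAddOns:
    def test_tax_credit_zero_rate_unchanged(self, base):
        s = base.model_copy(deep=True)
        s.commercial.tax_credit_rate = 0.0
        res = rnpv(s)
        assert apply_tax_credit(res, s).rnpv_overall == res.rnpv_overall

    def test_tax_credit_amount(self, base):
        res = rnpv(base)
        cred = apply_tax_credit(res, base)
        expected = 0.25 * res.components["credit_base_cost_pv"]
        assert cred.rnpv_overall - res.rnpv_overall == pytest.approx(expected)
        assert cred.components["tax_credit"] == pytest.approx(expected)

    def test_prv_zero_value_unchanged(self, base):
        s = base.model_copy(deep=True)
        s.commercial.prv_value = 0.0
        res = rnpv(s)
        assert apply_prv(res, s).rnpv_overall == res.rnpv_overall

    def test_prv_certain_undiscounted_adds_face_value(self, base):
        s = base.model_copy(deep=True)
        for ph in s.plan.phases:
            ph.pos = 1.0
        res = rnpv(s, discount_rate=0.0)
        got = apply_prv(res, s)
        assert got.rnpv_overall - res.rnpv_overall == pytest.approx(100.0)
        assert got.components["prv_survival"] == 1.0

    def test_prv_survival_counts_phases_completed_by_grant_year(self, base):
        res = apply_prv(rnpv(base), base)
        # phases ending by year 3: the first phase and phase 2
        assert res.components["prv_survival"] == pytest.approx(0.67 * 0.53)

    def test_prv_beyond_timeline_rejected(self, base):
        s = base.model_copy(deep=True)
        s.commercial.prv_year = 99.0
        with pytest.raises(ValueError, match="launch"):
            apply_prv(rnpv(s), s)

    def test_prv_end_timing_discounts_full_year(self, base):
        start = apply_prv(rnpv(base), base)
        conv = Conventions(prv_timing="end")
        end = apply_prv(rnpv(base, conventions=conv), base)
        ratio = (end.components["prv"]) / (start.components["prv"])
        assert ratio == pytest.approx(1 / 1.13)

    def test_flags_apply_addons(self, base):
        s = base.model_copy(deep=True)
        s.flags.include_tax_credit = True
        s.flags.include_prv = True
        res = rnpv(s)
        manual = apply_prv(apply_tax_credit(rnpv(base), base), base)
        assert res.rnpv_overall == pytest.approx(manual.rnpv_overall)
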