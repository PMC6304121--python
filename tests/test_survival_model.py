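"""Seasonal temperature model, metabolic states and the daily PHB budget."""

import math

import numpy as np
import pytest

from rhizophb.survival_model import (
    STATE_ORDER,
    STATES,
    CellParams,
    TemperatureModel,
    daily_phb_requirement,
    days_supported,
    fit_temperature_model,
    metabolic_rate,
    phb_biomass_fraction,
    phb_required,
    soil_temperature,
    survival_curve,
)


class TestSoilTemperature:
    def test_midpoint_at_delta(self):
        m = TemperatureModel(t_max=25, t_min=-3, delta=121)
        assert soil_temperature(121, m) == pytest.approx((25 - 3) / 2)

    def test_peak_a_quarter_cycle_after_delta(self):
        m = TemperatureModel(t_max=25, t_min=-3, delta=121)
        assert soil_temperature(121 + 365 / 4, m) == pytest.approx(25.0)
        assert soil_temperature(121 + 3 * 365 / 4, m) == pytest.approx(-3.0)

    def test_periodicity(self):
        m = TemperatureModel()
        days = np.arange(1, 366)
        np.testing.assert_allclose(
            soil_temperature(days, m), soil_temperature(days + 365, m),
            rtol=1e-12, atol=1e-9,
        )


class TestFitTemperatureModel:
    @staticmethod
    def monthly_from(model):
        days = (np.arange(1, 13) - 0.5) * 365 / 12
        return list(zip(range(1, 13), soil_temperature(days, model)))

    def test_exact_recovery_of_noiseless_sinusoid(self):
        truth = TemperatureModel(t_max=25, t_min=-3, delta=121)
        fit = fit_temperature_model(self.monthly_from(truth))
        assert not fit.degenerate
        assert fit.model.t_max == pytest.approx(25, abs=1e-6)
        assert fit.model.t_min == pytest.approx(-3, abs=1e-6)
        assert fit.model.delta == 121

    def test_waseca_like_extremes_recovered_under_noise(self):
        truth = TemperatureModel(t_max=25, t_min=-3, delta=121)
        rng = np.random.default_rng(4)
        noisy = [(m, t + rng.normal(0, 0.5)) for m, t in self.monthly_from(truth)]
        fit = fit_temperature_model(noisy)
        assert fit.model.t_max == pytest.approx(25, abs=1.5)
        assert fit.model.t_min == pytest.approx(-3, abs=1.5)

    def test_constant_series_is_degenerate(self):
        fit = fit_temperature_model([(m, 10.0) for m in range(1, 13)])
        assert fit.degenerate and fit.model is None


class TestMetabolicRates:
    def test_full_somatic_maintenance_intercept(self):
        assert metabolic_rate(0.0, "full_somatic_maintenance") == pytest.approx(
            10 ** -5.14, rel=1e-12
        )

    @pytest.mark.parametrize("temp", [-3.0, 0.0, 11.0, 25.0])
    def test_intermediate_states_are_exact_decades_of_fsm(self, temp):
        fsm = metabolic_rate(temp, "full_somatic_maintenance")
        assert metabolic_rate(temp, "intermediate_10pct") == pytest.approx(
            0.1 * fsm, rel=1e-12
        )
        assert metabolic_rate(temp, "intermediate_1pct") == pytest.approx(
            0.01 * fsm, rel=1e-12
        )
        assert metabolic_rate(temp, "intermediate_0.1pct") == pytest.approx(
            0.001 * fsm, rel=1e-12
        )

    def test_fsm_to_dormancy_span_at_zero_celsius(self):
        ratio = metabolic_rate(0, "full_somatic_maintenance") / metabolic_rate(
            0, "dormancy"
        )
        assert ratio == pytest.approx(10**3.03, rel=1e-12)

    def test_rates_increase_with_temperature(self):
        temps = np.linspace(-5, 30, 50)
        for state in STATE_ORDER:
            rates = metabolic_rate(temps, state)
            assert np.all(np.diff(rates) > 0)

    def test_intercept_offset_hook(self):
        shifted = STATES["dormancy"].with_offset(-0.5)
        assert metabolic_rate(10, shifted) == pytest.approx(
            10**-0.5 * metabolic_rate(10, "dormancy"), rel=1e-12
        )


class TestDailyRequirement:
    def test_dormancy_at_25C_hand_value(self):
        # 10^(0.084*25 - 8.17) * 0.5 * (96/150) / (48/86)
        expected = 10 ** (0.084 * 25 - 8.17) * 0.5 * (96 / 150) / (48 / 86)
        got = daily_phb_requirement(25.0, "dormancy")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(4.9e-7, rel=0.01)

    def test_linear_in_structural_biomass(self):
        small = daily_phb_requirement(10, "dormancy", CellParams(structural_biomass_pg=0.25))
        big = daily_phb_requirement(10, "dormancy", CellParams(structural_biomass_pg=0.5))
        assert big == pytest.approx(2 * small, rel=1e-12)

    def test_inverse_in_phb_carbon_fraction(self):
        base = CellParams()
        halved = CellParams(carbon_fraction_phb=base.carbon_fraction_phb / 2)
        assert daily_phb_requirement(10, "dormancy", halved) == pytest.approx(
            2.0 * daily_phb_requirement(10, "dormancy", base), rel=1e-12
        )


def oracle_budget(t, start_day, state, cell=CellParams(), model=TemperatureModel()):
    """Independent one-line-per-day accumulation of the daily budget."""
    st = STATES[state] if isinstance(state, str) else state
    terms = []
    for i in range(1, t + 1):
        temp = soil_temperature(start_day + i, model)
        m = 10.0 ** (st.alpha * temp + st.beta)
        terms.append(
            m * cell.structural_biomass_pg * cell.carbon_fraction_biomass
            / cell.carbon_fraction_phb
        )
    return math.fsum(terms)


class TestPhbRequired:
    def test_zero_duration_costs_nothing(self):
        assert phb_required(0, 258, "dormancy") == 0.0

    @pytest.mark.parametrize("state", STATE_ORDER)
    @pytest.mark.parametrize("start_day, duration", [(258, 608), (1, 100), (121, 1000)])
    def test_agrees_with_per_day_accumulation_oracle(self, state, start_day, duration):
        got = phb_required(duration, start_day, state)
        want = oracle_budget(duration, start_day, state)
        assert got == pytest.approx(want, rel=1e-12)

    def test_additivity_over_adjacent_windows(self):
        whole = phb_required(350, 258, "dormancy")
        split = phb_required(100, 258, "dormancy") + phb_required(
            250, 258 + 100, "dormancy"
        )
        assert whole == pytest.approx(split, rel=1e-12)

    def test_full_year_cost_is_start_day_invariant(self):
        costs = [phb_required(365, s, "intermediate_1pct") for s in (1, 60, 258, 300)]
        assert max(costs) == pytest.approx(min(costs), rel=1e-12)

    def test_twenty_month_dormancy_budget_below_printed_value(self):
        assert phb_required(608, 258, "dormancy") <= 0.0009

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            phb_required(-1, 258, "dormancy")


class TestDaysSupported:
    def test_zero_budget_zero_days(self):
        assert days_supported(0.0, 258, "dormancy").days == 0

    @pytest.mark.parametrize("n", [1, 17, 365, 366, 1000, 4000])
    def test_integer_round_trip_with_phb_required(self, n):
        for state in ("full_somatic_maintenance", "dormancy"):
            budget = phb_required(n, 258, state)
            res = days_supported(budget, 258, state)
            assert res.days == n
            assert not res.censored

    def test_monotone_in_budget(self):
        grid = np.logspace(-4, 0.5, 25)
        days = [days_supported(p, 258, "intermediate_10pct").days for p in grid]
        assert all(a <= b for a, b in zip(days, days[1:]))

    def test_states_ordered_slowest_lasts_longest(self):
        for phb in (0.01, 0.32, 1.0):
            d = [days_supported(phb, 258, s, max_days=10**9).days for s in STATE_ORDER]
            assert all(a <= b for a, b in zip(d, d[1:]))

    def test_censoring_at_max_days(self):
        res = days_supported(3.0, 258, "dormancy", max_days=1000)
        assert res.days == 1000
        assert res.censored


class TestSurvivalCurve:
    def test_single_point_grid_reduces_to_days_supported(self):
        [c] = survival_curve([0.32], states=["dormancy"])
        assert c.days[0] == days_supported(0.32, 258, "dormancy").days

    def test_curves_never_cross_across_states(self):
        grid = np.logspace(-3, 0.5, 12)
        curves = survival_curve(grid, states=STATE_ORDER, max_days=10**9)
        by_state = {c.state: np.array(c.days) for c in curves}
        for fast, slow in zip(STATE_ORDER, STATE_ORDER[1:]):
            assert np.all(by_state[fast] <= by_state[slow])

    def test_warmer_start_never_extends_survival(self):
        # starting into summer spends the budget faster than starting into
        # autumn; at matched PHB the days supported cannot increase
        grid = np.logspace(-3, -1.2, 8)
        autumn = survival_curve(grid, start_day=258, states=["intermediate_1pct"])[0]
        summer = survival_curve(grid, start_day=166, states=["intermediate_1pct"])[0]
        assert all(s <= a for s, a in zip(summer.days, autumn.days))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            survival_curve([])


def test_phb_biomass_fraction_arithmetic():
    assert phb_biomass_fraction(2.0, 0.5) == 0.8
    assert phb_biomass_fraction(0.0, 0.5) == 0.0
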