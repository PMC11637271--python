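"""DALY accounting: YLD accrual, YLL conventions, linearity properties."""

import pytest

from hernia_cea import PainDistribution, compute_yld, compute_yll, dalys_averted, run_cohort
from hernia_cea.outcomes import discounted_years, yld_literal, yll_value_per_death

from conftest import annuity


def _untreated_single_band(params, band, **overrides):
    p = params.copy()
    p.pre_op_pain = PainDistribution.degenerate(band)
    for key, value in overrides.items():
        obj = p
        *head, leaf = key.split(".")
        for part in head:
            obj = getattr(obj, part)
        setattr(obj, leaf, value)
    return p


class TestYld:
    def test_zero_weights_zero_yld(self, params_mut, zero_mortality_lt):
        params_mut.disability_weights.mild = 0.0
        params_mut.disability_weights.moderate = 0.0
        params_mut.disability_weights.severe = 0.0
        trace = run_cohort(params_mut, "NONE")
        assert compute_yld(trace, params_mut.disability_weights, params_mut.pre_op_pain) == 0.0

    @pytest.mark.parametrize("band,dw", [("severe", 0.3240), ("moderate", 0.1140)])
    def test_untreated_single_band_closed_form(self, params, zero_mortality_lt, band, dw):
        # no deaths, 10 years at 3% with correction: DW x mid-cycle annuity
        p = _untreated_single_band(params, band, **{"premature_death.p_complication": 0.0})
        p.life_table = zero_mortality_lt
        trace = run_cohort(p, "NONE")
        expected = dw * annuity(0.03, 10, "mid")
        assert trace.total_yld_disc == pytest.approx(expected, rel=1e-12)

    def test_zero_discount_exact_dw_times_horizon(self, params, zero_mortality_lt):
        p = _untreated_single_band(params, "severe", **{"premature_death.p_complication": 0.0})
        p.life_table = zero_mortality_lt
        p.settings.discount_rate = 0.0
        trace = run_cohort(p, "NONE")
        assert trace.total_yld_disc == pytest.approx(0.3240 * 10, rel=1e-12)

    def test_yld_linear_in_disability_weight(self, params, zero_mortality_lt):
        p = _untreated_single_band(params, "severe", **{"premature_death.p_complication": 0.0})
        p.life_table = zero_mortality_lt
        base = run_cohort(p, "NONE").total_yld_disc
        p.disability_weights.severe = 2 * 0.3240
        doubled = run_cohort(p, "NONE").total_yld_disc
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_repaired_state_uses_post_op_mix(self, params_mut, zero_mortality_lt):
        params_mut.life_table = zero_mortality_lt
        params_mut.strategies["AC"].p_recurrence = 0.0
        params_mut.strategies["AC"].p_contralateral = 0.0
        params_mut.post_op_pain = PainDistribution.degenerate("mild")
        trace = run_cohort(params_mut, "AC")
        # cycle 1 at pre-op mix, cycles 2..10 at chronic mild pain
        dw_pre = params_mut.pre_op_pain.mean_dw(params_mut.disability_weights)
        expected = dw_pre * annuity(0.03, 1, "mid") + 0.0110 * (
            annuity(0.03, 10, "mid") - annuity(0.03, 1, "mid")
        )
        assert trace.total_yld_disc == pytest.approx(expected, rel=1e-9)


class TestYll:
    def test_no_premature_death_no_yll(self, params_mut):
        params_mut.premature_death.p_complication = 0.0
        trace = run_cohort(params_mut, "NONE")
        assert trace.total_yll_disc == 0.0

    def test_treated_strategies_accrue_no_yll(self, params):
        for name in ("AC", "MD"):
            assert run_cohort(params, name).total_yll_disc == 0.0

    def test_full_le_death_at_cycle_one_undiscounted(self, params_mut):
        # one premature death in cycle 1 at zero discount, full-LE convention,
        # no half-cycle correction: loses the life expectancy at age 41
        params_mut.settings.discount_rate = 0.0
        params_mut.settings.half_cycle_correction = False
        params_mut.settings.yll_convention = "full_remaining_LE_discounted"
        value = yll_value_per_death(1, params_mut.settings, params_mut.life_table)
        assert value == pytest.approx(params_mut.life_table.ex_at(41), rel=1e-12)

    def test_horizon_capped_death_loses_remaining_cycles(self, params_mut):
        params_mut.settings.discount_rate = 0.0
        params_mut.settings.half_cycle_correction = False
        params_mut.settings.yll_convention = "horizon_capped"
        # death at end of cycle 4 of 10 loses cycles 5..10
        assert yll_value_per_death(4, params_mut.settings, params_mut.life_table) == pytest.approx(6.0)

    def test_yll_linear_in_premature_risk_at_operating_scale(self, params):
        # near the base-case risk (~0.1%/yr) YLL grows linearly; cohort
        # depletion makes it measurably sublinear (>1%) only above ~0.4%/yr
        def yll_at(p_complication):
            p = params.copy()
            p.premature_death.p_complication = p_complication
            p.premature_death.p_mortality_given_complication = 1.0
            return run_cohort(p, "NONE").total_yll_disc

        slope = yll_at(1e-6) / 1e-6
        assert yll_at(0.002) == pytest.approx(slope * 0.002, rel=0.01)
        assert yll_at(0.010) < slope * 0.010  # depletion bends the curve down

    def test_conventions_ordered(self, params):
        # full remaining life expectancy (~27 y) exceeds the in-horizon loss
        capped = params.copy()
        capped.settings.yll_convention = "horizon_capped"
        full = params.copy()
        full.settings.yll_convention = "full_remaining_LE_discounted"
        assert (
            run_cohort(full, "NONE").total_yll_disc > run_cohort(capped, "NONE").total_yll_disc
        )


class TestHelpers:
    def test_discounted_years_zero_rate(self):
        assert discounted_years(28.0, 0.0) == 28.0

    def test_discounted_years_shrinks_with_rate(self):
        assert 0 < discounted_years(28.0, 0.03) < 28.0

    def test_yld_literal_lifetime_formulation(self):
        assert yld_literal(0.114, 28.0) == pytest.approx(0.114 * 28.0)
        assert yld_literal(0.114, 28.0, rate=0.03) < yld_literal(0.114, 28.0)

    @pytest.mark.parametrize("a,b,expected", [(0.75, 0.09, 0.66), (2.9, 0.35, 2.55), (1.0, 1.0, 0.0)])
    def test_dalys_averted(self, a, b, expected):
        assert dalys_averted(a, b) == pytest.approx(expected)

    def test_daly_is_yld_plus_yll(self, params):
        trace = run_cohort(params, "NONE")
        assert trace.total_daly_disc == pytest.approx(
            trace.total_yld_disc + trace.total_yll_disc, abs=1e-12
        )
        yll = compute_yll(trace, params.life_table, params.settings)
        assert yll == pytest.approx(trace.total_yll_disc, rel=1e-12)
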