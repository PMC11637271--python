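"""Cohort engine: transition matrices, discounting, traces, half-cycle correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hernia_cea import StrategyParams, run_cohort
from hernia_cea.markov import (
    DEAD,
    NEW,
    REC,
    REP,
    apply_half_cycle_correction,
    build_transition_matrix,
    discount_factor,
)

from conftest import annuity


class TestDiscountFactor:
    def test_zero_rate_is_one(self):
        assert discount_factor(7, 0.0, "end") == 1.0

    def test_first_cycle_end(self):
        assert discount_factor(1, 0.03, "end") == pytest.approx(1 / 1.03)

    def test_ten_year_annuity(self):
        total = sum(discount_factor(t, 0.03, "end") for t in range(1, 11))
        assert total == pytest.approx(8.5302, abs=1e-4)

    def test_mid_timing_between_start_and_end(self):
        assert (
            discount_factor(3, 0.05, "end")
            < discount_factor(3, 0.05, "mid")
            < discount_factor(3, 0.05, "start")
        )

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.1)


class TestTransitionMatrix:
    def test_untreated_premature_death_entry(self, zero_mortality_lt):
        none = StrategyParams(provider="NONE")
        m = build_transition_matrix(none, 40, zero_mortality_lt, treated=False, p_premature_death=0.0011)
        assert m[NEW, DEAD] == pytest.approx(0.0011)
        assert m[NEW, NEW] == pytest.approx(1 - 0.0011)

    def test_all_risks_zero_identity_on_living(self, zero_mortality_lt):
        strat = StrategyParams(provider="NONE")
        m = build_transition_matrix(strat, 40, zero_mortality_lt, treated=False, p_premature_death=0.0)
        assert np.allclose(m, np.eye(4))

    def test_repaired_recurrence_entry(self, zero_mortality_lt):
        ac = StrategyParams(provider="AC", cost_per_procedure=149, p_recurrence=0.0092, p_contralateral=0.0038)
        m = build_transition_matrix(ac, 40, zero_mortality_lt, treated=True)
        # equal to the raw risks up to the competing-risk interaction (~0.3%)
        assert m[REP, REC] == pytest.approx(0.0092, rel=4e-3)
        assert m[REP, NEW] == pytest.approx(0.0038, rel=4e-3)
        assert m[REP, REC] + m[REP, NEW] == pytest.approx(
            1 - (1 - 0.0092) * (1 - 0.0038), abs=1e-15
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        p_rec=st.floats(0, 0.5),
        p_con=st.floats(0, 0.5),
        q=st.floats(0, 0.3),
        p_pd=st.floats(0, 0.05),
        treated=st.booleans(),
    )
    def test_rows_always_stochastic(self, p_rec, p_con, q, p_pd, treated):
        import pandas as pd

        from hernia_cea import LifeTable

        lt = LifeTable(pd.DataFrame({"age": [18, 90], "q": [q, q], "ex": [60.0, 5.0]}))
        strat = StrategyParams(provider="AC", p_recurrence=p_rec, p_contralateral=p_con)
        m = build_transition_matrix(strat, 40, lt, treated, 0.0 if treated else p_pd)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert ((m >= -1e-15) & (m <= 1 + 1e-15)).all()


class TestRunCohort:
    def test_no_exit_cohort_stays_in_new_hernia(self, params_mut, zero_mortality_lt):
        params_mut.life_table = zero_mortality_lt
        params_mut.premature_death.p_complication = 0.0
        trace = run_cohort(params_mut, "NONE")
        assert np.allclose(trace.df["occ_new_hernia"], 1.0)
        assert np.allclose(trace.df["occ_dead"], 0.0)

    @pytest.mark.parametrize("name", ["NONE", "AC", "MD"])
    def test_occupancy_conservation(self, params, name):
        trace = run_cohort(params, name)
        totals = trace.occupancy.sum(axis=1)
        assert np.allclose(totals, 1.0, atol=1e-9)

    @pytest.mark.parametrize("name", ["NONE", "AC", "MD"])
    def test_death_absorbing(self, params, name):
        trace = run_cohort(params, name)
        dead = trace.df["occ_dead"].to_numpy()
        assert (np.diff(dead) >= -1e-15).all()

    def test_zero_rate_no_correction_discounted_equals_undiscounted(self, params_mut):
        params_mut.settings.discount_rate = 0.0
        params_mut.settings.half_cycle_correction = False
        trace = run_cohort(params_mut, "AC")
        assert trace.df["cost_disc"].sum() == pytest.approx(trace.df["cost_undisc"].sum())
        assert trace.df["yld_disc"].sum() == pytest.approx(trace.df["yld_undisc"].sum())

    def test_trace_export_columns(self, params, tmp_path):
        trace = run_cohort(params, "AC")
        out = tmp_path / "trace.csv"
        trace.to_csv(out)
        header = out.read_text().splitlines()[0].split(",")
        for col in ("cycle", "age", "occ_repaired", "cost_disc", "yld_disc", "yll_disc"):
            assert col in header


class TestHalfCycleCorrection:
    def test_constant_occupancy_undiscounted_accrual_unchanged(self, params_mut, zero_mortality_lt):
        # no deaths: person-time equals occupancy whether or not HCC applies
        params_mut.life_table = zero_mortality_lt
        params_mut.premature_death.p_complication = 0.0
        params_mut.settings.half_cycle_correction = False
        uncorrected = run_cohort(params_mut, "NONE")
        corrected = apply_half_cycle_correction(uncorrected)
        assert corrected.df["yld_undisc"].sum() == pytest.approx(uncorrected.df["yld_undisc"].sum())

    def test_corrected_annuity_closed_form(self, params_mut, zero_mortality_lt):
        # a no-death cohort living at disability weight 1 accrues the
        # mid-cycle-discounted annuity when the correction is on
        params_mut.life_table = zero_mortality_lt
        params_mut.premature_death.p_complication = 0.0
        params_mut.disability_weights.mild = 1.0
        params_mut.disability_weights.moderate = 1.0
        params_mut.disability_weights.severe = 1.0
        trace = run_cohort(params_mut, "NONE")
        assert trace.df["yld_disc"].sum() == pytest.approx(annuity(0.03, 10, "mid"), abs=1e-9)
        # and close to the start/end-average convention (difference < 0.01%)
        assert trace.df["yld_disc"].sum() == pytest.approx(8.658, abs=2e-3)

    def test_apply_matches_direct_run(self, params_mut):
        params_mut.settings.half_cycle_correction = False
        uncorrected = run_cohort(params_mut, "MD")
        corrected = apply_half_cycle_correction(uncorrected)
        direct_params = params_mut.copy()
        direct_params.settings.half_cycle_correction = True
        direct = run_cohort(direct_params, "MD")
        assert corrected.total_cost_disc == pytest.approx(direct.total_cost_disc)
        assert corrected.total_daly_disc == pytest.approx(direct.total_daly_disc)

    def test_initial_procedure_cost_unaffected(self, params_mut):
        params_mut.strategies["AC"].p_recurrence = 0.0
        params_mut.strategies["AC"].p_contralateral = 0.0
        trace = run_cohort(params_mut, "AC")
        # one-off time-zero cost: no discounting, no half-cycle weighting
        assert trace.total_cost_disc == pytest.approx(149.0)
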