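"""DSA/tornado, PSA sampling and the acceptability curve."""

import numpy as np
import pytest

from hernia_cea import (
    DSASpec,
    ParameterError,
    PSADistribution,
    ceac,
    one_way_dsa,
    run_psa,
    sample_psa,
)
from hernia_cea.uncertainty import (
    PSAOutput,
    _icer_value,
    default_dsa_specs,
    resolve_path,
    set_path,
)


class TestParameterPaths:
    def test_resolve_and_set(self, params_mut):
        assert resolve_path(params_mut, "strategies.AC.cost_per_procedure") == 149
        set_path(params_mut, "strategies.AC.cost_per_procedure", 120.0)
        assert params_mut.strategies["AC"].cost_per_procedure == 120.0
        set_path(params_mut, "settings.half_cycle_correction", 0)
        assert params_mut.settings.half_cycle_correction is False

    @pytest.mark.parametrize("path", ["strategies.XX.cost", "settings.nonexistent", "nope"])
    def test_bad_paths_rejected(self, params_mut, path):
        with pytest.raises(ParameterError, match="resolve"):
            resolve_path(params_mut, path)


class TestDSA:
    def test_spec_requires_ordered_bounds(self):
        with pytest.raises(ParameterError, match="low <= base <= high"):
            DSASpec("settings.discount_rate", base=0.03, low=0.05, high=0.01)

    def test_degenerate_spec_zero_span(self, params):
        spec = DSASpec("strategies.AC.cost_per_procedure", base=149, low=149, high=149)
        (entry,) = one_way_dsa(params, [spec], comparison=("NONE", "AC"))
        assert entry.span == pytest.approx(0.0)

    def test_icer_scales_linearly_with_procedure_cost(self, params):
        # total cost is proportional to the procedure price, DALYs unchanged
        base = _icer_value(params, ("NONE", "AC"))
        spec = DSASpec("strategies.AC.cost_per_procedure", base=149, low=120, high=179)
        (entry,) = one_way_dsa(params, [spec], comparison=("NONE", "AC"))
        assert entry.icer_high / base == pytest.approx(179 / 149, rel=1e-9)
        assert entry.icer_low / base == pytest.approx(120 / 149, rel=1e-9)

    def test_spans_invariant_to_spec_order(self, params):
        specs = default_dsa_specs(params, ("NONE", "AC"))
        forward = one_way_dsa(params, specs, comparison=("NONE", "AC"))
        backward = one_way_dsa(params, list(reversed(specs)), comparison=("NONE", "AC"))
        assert [(e.label, e.span) for e in forward] == [(e.label, e.span) for e in backward]

    def test_entries_sorted_by_span(self, params):
        entries = one_way_dsa(params, comparison=("NONE", "MD"))
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)

    def test_discount_and_half_cycle_expressible(self, params):
        specs = [
            DSASpec("settings.discount_rate", base=0.03, low=0.0, high=0.035),
            DSASpec("settings.half_cycle_correction", base=1, low=0, high=1),
        ]
        entries = one_way_dsa(params, specs, comparison=("NONE", "AC"))
        assert len(entries) == 2
        assert all(np.isfinite([e.icer_low, e.icer_high]).all() for e in entries)


class TestPSASampling:
    def test_zero_sd_constant(self):
        draws = sample_psa([PSADistribution("disability_weights.moderate", 0.114, 0.0)], 50, seed=1)
        assert (draws["disability_weights.moderate"] == 0.114).all()

    def test_beta_moments_match(self):
        dist = PSADistribution("disability_weights.moderate", 0.1140, 0.0200, "beta")
        draws = sample_psa([dist], 100_000, seed=5)["disability_weights.moderate"]
        assert draws.mean() == pytest.approx(0.1140, abs=3 * 0.0200 / np.sqrt(100_000))
        assert draws.std() == pytest.approx(0.0200, rel=0.05)
        assert ((draws > 0) & (draws < 1)).all()

    def test_fixed_seed_reproducible(self):
        dists = [PSADistribution("disability_weights.severe", 0.324, 0.055)]
        a = sample_psa(dists, 200, seed=11)
        b = sample_psa(dists, 200, seed=11)
        assert a.equals(b)

    def test_incompatible_sd_falls_back_to_truncnorm(self):
        dist = PSADistribution("disability_weights.mild", 0.05, 0.40, "beta")
        with pytest.warns(UserWarning, match="truncated normal"):
            draws = sample_psa([dist], 500, seed=2)["disability_weights.mild"]
        assert ((draws >= 0) & (draws <= 1)).all()

    def test_invalid_draw_count(self):
        with pytest.raises(ParameterError):
            sample_psa([], 0, seed=1)


class TestRunPSA:
    def test_degenerate_psa_reproduces_deterministic(self, params):
        from hernia_cea import evaluate_strategy

        dists = [
            PSADistribution("disability_weights.moderate", 0.1140, 0.0),
            PSADistribution("strategies.AC.p_recurrence", 0.0092, 0.0),
        ]
        psa = run_psa(params, dists, n=1, seed=3, comparisons=(("NONE", "AC"),))
        inc = psa.increments[("NONE", "AC")]
        none = evaluate_strategy(params, "NONE")
        ac = evaluate_strategy(params, "AC")
        assert inc["d_cost"].iloc[0] == pytest.approx(ac.total_cost - none.total_cost)
        assert inc["d_daly"].iloc[0] == pytest.approx(none.total_daly - ac.total_daly)

    def test_frame_has_draw_columns(self, params):
        psa = run_psa(params, n=5, seed=9, comparisons=(("NONE", "AC"),))
        frame = psa.frame()
        assert len(frame) == 5
        assert "d_cost_AC_vs_NONE" in frame.columns and "draw" in frame.columns


class TestCEAC:
    def _toy_psa(self, d_cost, d_daly):
        import pandas as pd

        out = PSAOutput(n=len(d_cost), seed=0, parameter_draws=pd.DataFrame(index=range(len(d_cost))))
        out.increments[("NONE", "AC")] = pd.DataFrame({"d_cost": d_cost, "d_daly": d_daly})
        return out

    def test_zero_threshold_all_costlier(self):
        curve = ceac(self._toy_psa([10.0, 20.0], [0.5, 0.5]), thresholds=[0.0])
        assert curve["p_ce_AC_vs_NONE"].iloc[0] == 0.0

    def test_high_threshold_all_averting(self):
        curve = ceac(self._toy_psa([10.0, 20.0], [0.5, 0.5]), thresholds=[1e9])
        assert curve["p_ce_AC_vs_NONE"].iloc[0] == 1.0

    def test_monotone_when_all_draws_avert(self, params):
        psa = run_psa(params, n=100, seed=17, comparisons=(("NONE", "AC"),))
        curve = ceac(psa)
        p = curve["p_ce_AC_vs_NONE"].to_numpy()
        assert (np.diff(p) >= -1e-12).all()
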