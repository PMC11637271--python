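"""Cost-effectiveness analysis: ICERs, dominance, thresholds, subgroups.

Strategies are compared pairwise (repair by MDs or ACs vs. no repair, and
ACs vs. MDs) on total discounted cost and DALYs over the model horizon.
The ICER is the incremental cost per DALY averted; a strategy that is both
cheaper and averts more DALYs dominates.  Classification against the WHO
willingness-to-pay convention: very cost-effective below 1x GDP per capita,
cost-effective below 3x GDP per capita.

Subgroup analyses rerun the full pipeline with the pre-operative pain mix
degenerate at one band (moderate or severe); costs are unchanged by design
since disability does not enter the cost model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from scipy.optimize import brentq

from . import costing, outcomes
from .markov import CohortTrace, run_cohort
from .parameters import (
    PainDistribution,
    ParameterError,
    ParameterSet,
    ThresholdSet,
)

__all__ = [
    "StrategyOutcome",
    "CEAResult",
    "evaluate_strategy",
    "compare_strategies",
    "classify_against_threshold",
    "subgroup_cea",
    "full_cea",
    "CEAReport",
    "calibrate_pre_op_pain_mix",
]

#: Comparisons reported in the published layout: (comparator, strategy).
DEFAULT_COMPARISONS = (("NONE", "MD"), ("NONE", "AC"), ("MD", "AC"))

SUBGROUP_BANDS = ("moderate", "severe")


@dataclass
class StrategyOutcome:
    """Total discounted cost and DALYs for one strategy."""

    name: str
    cost: costing.CostResult
    daly: outcomes.DalyResult
    trace: Optional[CohortTrace] = None

    @property
    def total_cost(self) -> float:
        return self.cost.total

    @property
    def total_daly(self) -> float:
        return self.daly.daly


def evaluate_strategy(params: ParameterSet, name: str) -> StrategyOutcome:
    """Run the cohort model for one strategy and summarize cost and DALYs."""
    strategy = params.strategies[name]
    trace = run_cohort(params, strategy)
    cost = costing.cohort_cost(trace, strategy, params.settings)
    daly = outcomes.DalyResult(
        yld=trace.total_yld_disc,
        yll=trace.total_yll_disc,
        per_cycle=trace.df[["cycle", "yld_disc", "yll_disc"]].copy(),
    )
    return StrategyOutcome(name=name, cost=cost, daly=daly, trace=trace)


@dataclass
class CEAResult:
    """Pairwise comparison of a strategy against a comparator."""

    comparator: str
    strategy: str
    cost_comparator: float
    cost_strategy: float
    daly_comparator: float
    daly_strategy: float
    incremental_cost: float
    dalys_averted: float
    icer: Optional[float]
    classification: str

    def as_dict(self) -> dict:
        return {
            "comparator": self.comparator,
            "strategy": self.strategy,
            "cost_comparator": self.cost_comparator,
            "cost_strategy": self.cost_strategy,
            "daly_comparator": self.daly_comparator,
            "daly_strategy": self.daly_strategy,
            "incremental_cost": self.incremental_cost,
            "dalys_averted": self.dalys_averted,
            "icer": self.icer,
            "classification": self.classification,
        }


def classify_against_threshold(icer: float, thresholds: ThresholdSet) -> str:
    """WHO-convention classification of an ICER (USD per DALY averted).

    Below GDP per capita: very cost-effective; from GDP up to (but not at)
    3x GDP: cost-effective; otherwise not.  Boundaries round up to the less
    favourable class.
    """
    if icer < thresholds.gdp_per_capita:
        return "very_cost_effective"
    if icer < thresholds.wtp:
        return "cost_effective"
    return "not_cost_effective"


def compare_strategies(
    result_a: StrategyOutcome | tuple[float, float],
    result_b: StrategyOutcome | tuple[float, float],
    thresholds: Optional[ThresholdSet] = None,
    names: tuple[str, str] = ("comparator", "strategy"),
) -> CEAResult:
    """Incremental comparison of strategy b against comparator a.

    Accepts either StrategyOutcome objects or bare (cost, daly) tuples.
    """
    if isinstance(result_a, StrategyOutcome):
        name_a, cost_a, daly_a = result_a.name, result_a.total_cost, result_a.total_daly
    else:
        cost_a, daly_a = result_a
        name_a = names[0]
    if isinstance(result_b, StrategyOutcome):
        name_b, cost_b, daly_b = result_b.name, result_b.total_cost, result_b.total_daly
    else:
        cost_b, daly_b = result_b
        name_b = names[1]

    d_cost = cost_b - cost_a
    averted = outcomes.dalys_averted(daly_a, daly_b)
    icer: Optional[float] = None
    if abs(d_cost) < 1e-12 and abs(averted) < 1e-12:
        classification = "indifferent"
    elif d_cost <= 0 and averted > 0 or (d_cost < 0 and averted >= 0):
        classification = "dominant"
    elif d_cost >= 0 and averted < 0 or (d_cost > 0 and averted <= 0):
        classification = "dominated"
    else:
        icer = d_cost / averted
        thresholds = thresholds or ThresholdSet()
        classification = classify_against_threshold(icer, thresholds)
    return CEAResult(
        comparator=name_a,
        strategy=name_b,
        cost_comparator=cost_a,
        cost_strategy=cost_b,
        daly_comparator=daly_a,
        daly_strategy=daly_b,
        incremental_cost=d_cost,
        dalys_averted=averted,
        icer=icer,
        classification=classification,
    )


def _with_pre_op_pain(params: ParameterSet, pain: PainDistribution) -> ParameterSet:
    p = params.copy()
    p.pre_op_pain = pain.validate("pain_distributions.pre_op")
    return p


def subgroup_cea(pain_band: str, params: ParameterSet) -> dict[tuple[str, str], CEAResult]:
    """Rerun all default comparisons with pre-operative pain fixed at one band."""
    if pain_band not in SUBGROUP_BANDS:
        raise ParameterError(f"subgroup band must be one of {SUBGROUP_BANDS}, got {pain_band!r}")
    sub = _with_pre_op_pain(params, PainDistribution.degenerate(pain_band))
    outcomes_by_name = {n: evaluate_strategy(sub, n) for n in ("NONE", "MD", "AC")}
    return {
        (a, b): compare_strategies(outcomes_by_name[a], outcomes_by_name[b], sub.thresholds)
        for a, b in DEFAULT_COMPARISONS
    }


@dataclass
class CEAReport:
    """Base case plus pain-severity subgroup panels."""

    panels: dict = field(default_factory=dict)  # panel -> {"outcomes": ..., "comparisons": ...}

    def frame(self) -> pd.DataFrame:
        """Tabular report mirroring the published layout.

        Costs rounded to whole USD, DALYs to 2 decimals, ICERs to whole USD
        (internal math is full precision).
        """
        rows = []
        for panel, content in self.panels.items():
            for (a, b), res in content["comparisons"].items():
                icer = (
                    "Dominates"
                    if res.classification == "dominant"
                    else (round(res.icer) if res.icer is not None else res.classification)
                )
                rows.append(
                    {
                        "panel": panel,
                        "comparison": f"{b} vs {a}",
                        "cost_comparator": round(res.cost_comparator),
                        "cost_strategy": round(res.cost_strategy),
                        "daly_comparator": round(res.daly_comparator, 2),
                        "daly_strategy": round(res.daly_strategy, 2),
                        "incremental_cost": round(res.incremental_cost),
                        "dalys_averted": round(res.dalys_averted, 2),
                        "icer": icer,
                        "classification": res.classification,
                    }
                )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            panel: {
                "outcomes": {
                    n: {"total_cost": o.total_cost, "total_daly": o.total_daly}
                    for n, o in content["outcomes"].items()
                },
                "comparisons": {
                    f"{b}_vs_{a}": res.as_dict() for (a, b), res in content["comparisons"].items()
                },
            }
            for panel, content in self.panels.items()
        }


def full_cea(params: ParameterSet) -> CEAReport:
    """Base-case and subgroup cost-effectiveness analysis."""
    report = CEAReport()
    panel_params = {"base": params}
    for band in SUBGROUP_BANDS:
        panel_params[band] = _with_pre_op_pain(params, PainDistribution.degenerate(band))
    for panel, p in panel_params.items():
        outs = {n: evaluate_strategy(p, n) for n in ("NONE", "MD", "AC")}
        comps = {
            (a, b): compare_strategies(outs[a], outs[b], p.thresholds)
            for a, b in DEFAULT_COMPARISONS
        }
        report.panels[panel] = {"outcomes": outs, "comparisons": comps}
    return report


def calibrate_pre_op_pain_mix(
    params: ParameterSet, target_no_repair_daly: float = 0.75
) -> PainDistribution:
    """Solve the base-case pre-operative mild/moderate mix.

    The published base case does not print the pre-operative pain mix; this
    finds the mild/moderate split whose untreated-cohort DALY total over the
    horizon equals the published value (0.75 by default).  The result ships
    as the package default.
    """

    def daly_at(frac_moderate: float) -> float:
        mix = PainDistribution(mild=1.0 - frac_moderate, moderate=frac_moderate)
        p = _with_pre_op_pain(params, mix)
        return evaluate_strategy(p, "NONE").total_daly - target_no_repair_daly

    lo, hi = daly_at(0.0), daly_at(1.0)
    if lo * hi > 0:
        raise ParameterError(
            f"target DALY {target_no_repair_daly} not bracketed by mild/moderate mix "
            f"(range {lo + target_no_repair_daly:.3f}..{hi + target_no_repair_daly:.3f})"
        )
    f = brentq(daly_at, 0.0, 1.0, xtol=1e-10)
    return PainDistribution(mild=1.0 - f, moderate=f)
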