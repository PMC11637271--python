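"""DALY accounting: years lived with disability and years of life lost.

YLD accrues per cycle as occupancy-weighted mean disability weight times
person-time: hernia states (new or recurrent) carry the pre-operative pain
mix, REPAIRED carries the post-operative mix.  YLL accrues only from
premature hernia deaths (background deaths lose no life years — a model
convention required to reproduce the published untreated totals), valued
either as the discounted years remaining inside the model horizon
(``horizon_capped``, the default) or as the full discounted remaining life
expectancy at the age of death (``full_remaining_LE_discounted``).

The published YLD definition (disability weight x remaining life expectancy
at surgery) is a lifetime formulation that contradicts a 10-year horizon;
``yld_literal`` exposes it for comparison, while the model itself uses
per-cycle accrual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .markov import discount_factor
from .parameters import (
    DisabilityWeights,
    LifeTable,
    ModelSettings,
    PainDistribution,
    ParameterSet,
    StrategyParams,
)

__all__ = [
    "DalyResult",
    "compute_yld",
    "compute_yll",
    "dalys_averted",
    "yld_literal",
    "discounted_years",
    "yll_value_per_death",
    "attach_health",
]


@dataclass
class DalyResult:
    """Discounted YLD/YLL totals with the per-cycle decomposition."""

    yld: float
    yll: float
    per_cycle: pd.DataFrame

    @property
    def daly(self) -> float:
        return self.yld + self.yll


def discounted_years(n_years: float, rate: float) -> float:
    """Present value, at the moment they begin, of ``n_years`` of life.

    Continuous-flow convention: integral of (1+rate)^-t over [0, n].
    """
    if n_years <= 0:
        return 0.0
    if rate == 0:
        return float(n_years)
    log1p = math.log1p(rate)
    return (1.0 - (1.0 + rate) ** (-n_years)) / log1p


def yld_literal(dw: float, remaining_life_expectancy: float, rate: float = 0.0) -> float:
    """The lifetime YLD formulation: DW x (discounted) remaining life expectancy."""
    return dw * discounted_years(remaining_life_expectancy, rate)


def yll_value_per_death(
    cycle: int, settings: ModelSettings, life_table: LifeTable, discounted: bool = True
) -> float:
    """Life-years lost by one premature death during a given cycle.

    Shared by the cohort engine and the microsimulation oracle so both value
    deaths identically.  Under the half-cycle correction deaths occur
    mid-cycle; without it, at the cycle end.
    """
    rate = settings.discount_rate if discounted else 0.0
    hcc = settings.half_cycle_correction
    timing = settings.state_timing
    h = settings.horizon
    if settings.yll_convention == "horizon_capped":
        tail = sum(discount_factor(u, rate, timing) for u in range(cycle + 1, h + 1))
        if hcc:
            # the half cycle not lived, valued at this cycle's mid-point
            tail += 0.5 * discount_factor(cycle, rate, timing)
        return tail
    # full_remaining_LE_discounted
    age_at_death = settings.starting_age + (cycle - 1) + (0.5 if hcc else 1.0)
    ex = life_table.ex_at(age_at_death)
    return discounted_years(ex, rate) * discount_factor(cycle, rate, timing)


def compute_yld(
    trace,
    dws: DisabilityWeights,
    pre_op_pain: PainDistribution,
    post_op_pain: PainDistribution | None = None,
    discounted: bool = True,
) -> float:
    """Total YLD of a cohort trace under the given pain mixes."""
    post_op_pain = post_op_pain or PainDistribution(none=1.0)
    dw_pre = pre_op_pain.mean_dw(dws)
    dw_post = post_op_pain.mean_dw(dws)
    df = trace.df
    per_cycle = (df["pt_new_hernia"] + df["pt_recurrent_hernia"]) * dw_pre + df[
        "pt_repaired"
    ] * dw_post
    if discounted:
        per_cycle = per_cycle * df["disc_state"]
    return float(per_cycle.sum())


def compute_yll(trace, life_table: LifeTable, settings: ModelSettings, discounted: bool = True) -> float:
    """Total YLL from premature hernia deaths recorded in the trace."""
    life_table.require_coverage(settings.starting_age, settings.starting_age + settings.horizon)
    total = 0.0
    for cycle, deaths in zip(trace.df["cycle"], trace.df["premature_deaths"]):
        if deaths > 0:
            total += deaths * yll_value_per_death(int(cycle), settings, life_table, discounted)
    return total


def dalys_averted(daly_comparator: float, daly_strategy: float) -> float:
    """DALYs averted by a strategy relative to a comparator (positive = gain)."""
    return daly_comparator - daly_strategy


def attach_health(trace, params: ParameterSet, strategy: StrategyParams) -> DalyResult:
    """Fill the trace's per-cycle YLD/YLL columns and return the totals."""
    dws = params.disability_weights
    dw_pre = params.pre_op_pain.mean_dw(dws)
    dw_post = params.post_op_pain.mean_dw(dws)
    df = trace.df
    hernia_pt = df["pt_new_hernia"] + df["pt_recurrent_hernia"]
    yld_undisc = hernia_pt * dw_pre + df["pt_repaired"] * dw_post
    df["yld_undisc"] = yld_undisc
    df["yld_disc"] = yld_undisc * df["disc_state"]
    settings = params.settings
    df["yll_undisc"] = [
        d * yll_value_per_death(int(c), settings, params.life_table, discounted=False) if d > 0 else 0.0
        for c, d in zip(df["cycle"], df["premature_deaths"])
    ]
    df["yll_disc"] = [
        d * yll_value_per_death(int(c), settings, params.life_table, discounted=True) if d > 0 else 0.0
        for c, d in zip(df["cycle"], df["premature_deaths"])
    ]
    per_cycle = df[["cycle", "yld_disc", "yll_disc"]].copy()
    return DalyResult(
        yld=float(df["yld_disc"].sum()), yll=float(df["yll_disc"].sum()), per_cycle=per_cycle
    )
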