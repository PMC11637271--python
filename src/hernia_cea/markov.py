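"""Four-state annual-cycle Markov cohort engine.

States: NEW_HERNIA, RECURRENT_HERNIA, REPAIRED, DEAD (absorbing).  The
cohort enters at 100% NEW_HERNIA at the starting age.  Under a treatment
strategy the cohort spends its first cycle at pre-operative disability
(trial outcomes were measured one year after surgery) and occupies
REPAIRED from cycle 2; recurrent and contralateral hernias spend one cycle
at pre-operative pain and are re-repaired in that cycle.  Untreated hernia
states face background mortality plus the premature-death risk of an
unrepaired hernia; REPAIRED faces background mortality only.

Model conventions (documented in docs/methods.md):

* half-cycle correction: membership during a cycle is the start-of-cycle
  occupancy, deaths within the cycle count half a cycle of membership, and
  accruals are valued at the mid-cycle discount factor;
* the initial procedure is charged at time zero, undiscounted;
* background deaths accrue no years of life lost — only premature hernia
  deaths do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import LifeTable, ModelSettings, ParameterSet, StrategyParams

__all__ = [
    "NEW",
    "REC",
    "REP",
    "DEAD",
    "STATE_NAMES",
    "ModelSpecificationError",
    "discount_factor",
    "event_discount_timing",
    "build_transition_matrix",
    "CohortTrace",
    "run_cohort",
    "apply_half_cycle_correction",
]

NEW, REC, REP, DEAD = 0, 1, 2, 3
STATE_NAMES = ("new_hernia", "recurrent_hernia", "repaired", "dead")

_TIMING_OFFSET = {"start": 1.0, "mid": 0.5, "end": 0.0}


class ModelSpecificationError(ValueError):
    """Transition probabilities combined to an invalid row."""


def event_discount_timing(settings: ModelSettings) -> str:
    """Discount timing for in-cycle events (re-repairs).

    A recurrent or contralateral hernia arose during the preceding year and
    presents at the cycle boundary, where it is re-repaired: under the
    half-cycle correction events are valued at the cycle start; without it,
    everything is valued at the cycle end (classic uncorrected model).
    """
    return "start" if settings.half_cycle_correction else "end"


def discount_factor(cycle_index: int, rate: float, timing: str = "end") -> float:
    """(1+rate)^-t for cycle ``cycle_index`` (1-based) under a timing convention.

    ``start`` values the cycle at its opening instant (t = cycle-1), ``mid``
    at its midpoint and ``end`` at its close.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if timing not in _TIMING_OFFSET:
        raise ValueError(f"unknown discount timing {timing!r}")
    t = cycle_index - _TIMING_OFFSET[timing]
    return float((1.0 + rate) ** (-t))


def _split_union(p_a: float, p_b: float) -> tuple[float, float]:
    """Combine two independent per-cycle event risks.

    Returns effective exclusive probabilities allocating the union
    1-(1-p_a)(1-p_b) proportionally to the raw rates, so the tie-break
    order is irrelevant by construction.
    """
    total_raw = p_a + p_b
    if total_raw == 0.0:
        return 0.0, 0.0
    union = 1.0 - (1.0 - p_a) * (1.0 - p_b)
    return union * p_a / total_raw, union * p_b / total_raw


def build_transition_matrix(
    strategy: StrategyParams,
    age: float,
    life_table: LifeTable,
    treated: bool,
    p_premature_death: float = 0.0,
) -> np.ndarray:
    """Per-cycle 4x4 transition matrix at a given cohort age.

    Untreated hernia states combine background mortality q with the
    premature-death risk multiplicatively (independent risks) and otherwise
    stay put.  Treated hernia states are repaired within the cycle, so their
    survivors carry the same recurrence/contralateral risks as REPAIRED (the
    trial measured recurrence within one year of surgery): to
    RECURRENT_HERNIA on recurrence, back to NEW_HERNIA on a contralateral
    hernia, otherwise to REPAIRED.
    """
    life_table.require_coverage(age, age)
    q = life_table.q_at(age)
    m = np.zeros((4, 4))
    p_rec_eff, p_con_eff = _split_union(strategy.p_recurrence, strategy.p_contralateral)
    if treated:
        for state in (NEW, REC):
            m[state, DEAD] = q
            m[state, REC] = (1.0 - q) * p_rec_eff
            m[state, NEW] = (1.0 - q) * p_con_eff
            m[state, REP] = (1.0 - q) * (1.0 - p_rec_eff - p_con_eff)
    else:
        p_die = 1.0 - (1.0 - q) * (1.0 - p_premature_death)
        m[NEW, DEAD] = p_die
        m[NEW, NEW] = 1.0 - p_die
        m[REC, DEAD] = p_die
        m[REC, REC] = 1.0 - p_die
    m[REP, DEAD] = q
    m[REP, REC] = (1.0 - q) * p_rec_eff
    m[REP, NEW] = (1.0 - q) * p_con_eff
    m[REP, REP] = (1.0 - q) * (1.0 - p_rec_eff - p_con_eff)
    m[DEAD, DEAD] = 1.0
    if (m < -1e-12).any() or (m > 1.0 + 1e-12).any():
        raise ModelSpecificationError(f"transition probabilities out of [0, 1]:\n{m}")
    rows = m.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise ModelSpecificationError(f"transition rows must sum to 1, got {rows}")
    return m


@dataclass
class CohortTrace:
    """Per-cycle cohort bookkeeping.

    ``df`` has one row per cycle with start-of-cycle occupancy (fractions),
    death-adjusted person-time per living state, event counts (initial
    repairs, re-repairs, premature and background deaths), the discount
    factors applied to state accruals and events, and — once the costing
    and outcomes modules have run — per-cycle cost/YLD/YLL accruals,
    discounted and undiscounted.
    """

    df: pd.DataFrame
    strategy_name: str
    settings: ModelSettings
    params: ParameterSet

    @property
    def occupancy(self) -> pd.DataFrame:
        return self.df[["occ_" + s for s in STATE_NAMES]]

    @property
    def total_cost_disc(self) -> float:
        return float(self.df["cost_disc"].sum())

    @property
    def total_yld_disc(self) -> float:
        return float(self.df["yld_disc"].sum())

    @property
    def total_yll_disc(self) -> float:
        return float(self.df["yll_disc"].sum())

    @property
    def total_daly_disc(self) -> float:
        return self.total_yld_disc + self.total_yll_disc

    def to_csv(self, path) -> None:
        cols = [
            "cycle",
            "age",
            *("occ_" + s for s in STATE_NAMES),
            "cost_disc",
            "yld_disc",
            "yll_disc",
        ]
        extra = [c for c in self.df.columns if c not in cols]
        self.df[cols + extra].to_csv(path, index=False)


def run_cohort(params: ParameterSet, strategy: StrategyParams | str) -> CohortTrace:
    """Simulate the cohort under one strategy and attach cost and DALY accruals."""
    from . import costing, outcomes  # deferred: those modules import parameters only

    if isinstance(strategy, str):
        strategy = params.strategies[strategy]
    settings = params.settings
    life_table = params.life_table
    treated = strategy.treated
    p_pd = params.p_premature_death if not treated else 0.0

    timing = settings.state_timing
    h = settings.horizon
    s = np.zeros(4)
    s[NEW] = 1.0
    rows = []
    for t in range(1, h + 1):
        age = settings.starting_age + (t - 1)
        m = build_transition_matrix(strategy, age, life_table, treated, p_pd)
        death_probs = m[:, DEAD]
        if settings.half_cycle_correction:
            pt = s[:DEAD] * (1.0 - 0.5 * death_probs[:DEAD])
        else:
            pt = s[:DEAD].copy()
        hernia_occ = s[NEW] + s[REC]
        premature = 0.0 if treated else hernia_occ * p_pd
        background = float(s[:DEAD] @ death_probs[:DEAD]) - premature
        initial_repairs = 1.0 if (treated and t == 1) else 0.0
        re_repairs = hernia_occ if (treated and t >= 2) else 0.0
        rows.append(
            {
                "cycle": t,
                "age": age,
                "occ_new_hernia": s[NEW],
                "occ_recurrent_hernia": s[REC],
                "occ_repaired": s[REP],
                "occ_dead": s[DEAD],
                "pt_new_hernia": pt[NEW],
                "pt_recurrent_hernia": pt[REC],
                "pt_repaired": pt[REP],
                "premature_deaths": premature,
                "background_deaths": background,
                "initial_repairs": initial_repairs,
                "re_repairs": re_repairs,
                "disc_state": discount_factor(t, settings.discount_rate, timing),
                "disc_event": discount_factor(
                    t, settings.discount_rate, event_discount_timing(settings)
                ),
            }
        )
        s = s @ m
    df = pd.DataFrame(rows)
    trace = CohortTrace(df=df, strategy_name=strategy.provider, settings=settings, params=params)
    costing.attach_costs(trace, strategy, settings)
    outcomes.attach_health(trace, params, strategy)
    return trace


def apply_half_cycle_correction(trace: CohortTrace) -> CohortTrace:
    """Re-run the trace's cohort with the half-cycle correction enabled.

    Intended for traces produced with ``half_cycle_correction=False``; state
    membership is re-valued at the average of start- and end-of-cycle
    exposure (mid-cycle timing, half-cycle credit for within-cycle deaths)
    while the time-zero procedure cost is unaffected.
    """
    params = trace.params.copy()
    params.settings.half_cycle_correction = True
    params.settings.discount_timing = trace.settings.discount_timing
    return run_cohort(params, trace.strategy_name)
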