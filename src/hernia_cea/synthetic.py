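"""Synthetic trial cohorts, a microsimulation oracle and stub life tables.

Everything here exists so the full pipeline runs with no external data:

* ``generate_trial_cohort`` emulates the source randomized trial at the
  individual level — pre-/post-operative IPQ pain scores, one-year
  recurrence indicators at the provider-specific rates, and independent
  post-operative complication flags;
* ``estimate_parameters`` closes the recovery loop with maximum-likelihood
  proportions and binomial confidence intervals;
* ``microsim_oracle`` pushes n individuals through the identical state
  logic with per-individual random transitions, providing an independent
  check on the cohort engine's expected cost and DALYs;
* ``generate_life_table`` builds a Gompertz-parameterized mortality grid
  scaled to a chosen remaining life expectancy at age 40 — a SYNTHETIC
  stand-in for WHO country life tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from statsmodels.stats.proportion import proportion_confint

from .markov import (
    DEAD,
    NEW,
    REC,
    REP,
    build_transition_matrix,
    discount_factor,
    event_discount_timing,
)
from .outcomes import yll_value_per_death
from .parameters import (
    COMPLICATIONS,
    IPQ_BANDS,
    PAIN_BANDS,
    LifeTable,
    PainDistribution,
    ParameterError,
    ParameterSet,
    StrategyParams,
)

__all__ = [
    "generate_trial_cohort",
    "estimate_parameters",
    "MicrosimResult",
    "microsim_oracle",
    "generate_life_table",
]

#: IPQ scores belonging to each pain band (band 1 = no pain, 2-3 mild, ...).
BAND_SCORES = {"none": (1,), "mild": (2, 3), "moderate": (4, 5), "severe": (6, 7)}


def _sample_ipq(pain: PainDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw IPQ scores: band by the mix fractions, then uniform within band."""
    probs = np.array([getattr(pain, b) for b in PAIN_BANDS])
    bands = rng.choice(len(PAIN_BANDS), size=n, p=probs / probs.sum())
    scores = np.empty(n, dtype=int)
    for i, band in enumerate(PAIN_BANDS):
        mask = bands == i
        if mask.any():
            scores[mask] = rng.choice(BAND_SCORES[band], size=int(mask.sum()))
    return scores


def generate_trial_cohort(
    n: int,
    provider_mix: float,
    rates: dict[str, StrategyParams],
    pain: tuple[PainDistribution, PainDistribution],
    seed: int,
) -> pd.DataFrame:
    """Individual-level trial-like cohort.

    ``provider_mix`` is the fraction allocated to ACs; ``rates`` maps
    provider name to its StrategyParams (recurrence and complication
    probabilities); ``pain`` is the (pre-operative, post-operative) mix.
    Reproducible under a fixed seed.
    """
    if n <= 0:
        raise ParameterError(f"cohort size must be > 0, got {n}")
    if not (0.0 <= provider_mix <= 1.0):
        raise ParameterError(f"provider_mix must be in [0, 1], got {provider_mix}")
    rng = np.random.default_rng(seed)
    pre, post = pain
    pre.validate("pre_op_pain")
    post.validate("post_op_pain")
    provider = np.where(rng.random(n) < provider_mix, "AC", "MD")
    pre_ipq = _sample_ipq(pre, n, rng)
    post_ipq = _sample_ipq(post, n, rng)
    recurrence = np.zeros(n, dtype=bool)
    comp_flags = {c: np.zeros(n, dtype=bool) for c in COMPLICATIONS}
    for name in ("AC", "MD"):
        mask = provider == name
        strat = rates[name]
        m = int(mask.sum())
        recurrence[mask] = rng.random(m) < strat.p_recurrence
        for comp in COMPLICATIONS:
            comp_flags[comp][mask] = rng.random(m) < strat.complication_rates.get(comp, 0.0)
    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "provider": provider,
            "pre_op_ipq": pre_ipq,
            "post_op_ipq": post_ipq,
            "recurrence_within_1y": recurrence,
        }
    )
    for comp in COMPLICATIONS:
        df[comp] = comp_flags[comp]
    return df


def _proportion(successes: int, total: int) -> dict:
    est = successes / total
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="wilson")
    return {"estimate": float(est), "ci_low": float(lo), "ci_high": float(hi), "n": int(total)}


def estimate_parameters(cohort: pd.DataFrame) -> dict:
    """ML proportion estimates with 95% Wilson CIs, per provider.

    Returns ``{provider: {"p_recurrence": {...}, "complication_rates": {...},
    "pre_op_pain": PainDistribution, "post_op_pain": PainDistribution}}``.
    """
    out = {}
    for name, group in cohort.groupby("provider"):
        n = len(group)
        if n == 0:
            raise ParameterError(f"empty stratum for provider {name!r}")
        est = {
            "p_recurrence": _proportion(int(group["recurrence_within_1y"].sum()), n),
            "complication_rates": {
                c: _proportion(int(group[c].sum()), n) for c in COMPLICATIONS if c in group
            },
        }
        for which in ("pre_op", "post_op"):
            scores = group[f"{which}_ipq"]
            fractions = {
                band: float(scores.isin(BAND_SCORES[band]).mean()) for band in PAIN_BANDS
            }
            est[f"{which}_pain"] = PainDistribution(**fractions)
        out[name] = est
    if not out:
        raise ParameterError("cohort is empty")
    return out


@dataclass
class MicrosimResult:
    """Monte-Carlo means and standard errors from the individual-level oracle."""

    mean_cost: float
    mean_daly: float
    se_cost: float
    se_daly: float
    n: int


def microsim_oracle(
    params: ParameterSet, strategy: StrategyParams | str, n: int, seed: int
) -> MicrosimResult:
    """Individual-level re-implementation of the cohort model.

    Pushes ``n`` individuals through the same transition matrices with
    random per-individual transitions, valuing costs and DALYs with the
    identical conventions (time-zero procedure cost, in-cycle re-repairs,
    mid-cycle discounting under the half-cycle correction, half-cycle
    credit for within-cycle deaths, premature-death YLL).  Serves as an
    independent oracle for the deterministic cohort engine; expectation
    equals the cohort totals by construction.
    """
    if n <= 0:
        raise ParameterError(f"microsimulation size must be > 0, got {n}")
    if isinstance(strategy, str):
        strategy = params.strategies[strategy]
    settings = params.settings
    rng = np.random.default_rng(seed)
    treated = strategy.treated
    p_pd = params.p_premature_death if not treated else 0.0
    timing = settings.state_timing
    hcc = settings.half_cycle_correction

    from .costing import expected_complication_cost

    per_event = strategy.cost_per_procedure + expected_complication_cost(strategy)
    dw_pre = params.pre_op_pain.mean_dw(params.disability_weights)
    dw_post = params.post_op_pain.mean_dw(params.disability_weights)
    dw_by_state = np.array([dw_pre, dw_pre, dw_post, 0.0])

    state = np.full(n, NEW, dtype=np.int64)
    cost = np.full(n, per_event if treated else 0.0)  # initial repair at time 0
    daly = np.zeros(n)
    for t in range(1, settings.horizon + 1):
        age = settings.starting_age + (t - 1)
        m = build_transition_matrix(strategy, age, params.life_table, treated, p_pd)
        cum = np.cumsum(m, axis=1)
        d_state = discount_factor(t, settings.discount_rate, timing)
        d_event = discount_factor(t, settings.discount_rate, event_discount_timing(settings))
        alive = state != DEAD
        # re-repair charge for hernia occupants from cycle 2 (cohort convention:
        # charged for all occupants of the cycle, valued at presentation)
        if treated and t >= 2:
            hernia = alive & ((state == NEW) | (state == REC))
            cost[hernia] += per_event * d_event
        nxt = state.copy()
        if alive.any():
            u = rng.random(int(alive.sum()))
            nxt[alive] = np.argmax(u[:, None] < cum[state[alive]], axis=1)
        died = alive & (nxt == DEAD)
        exposure = np.where(died, 0.5 if hcc else 1.0, 1.0)
        daly[alive] += dw_by_state[state[alive]] * exposure[alive] * d_state
        if not treated and p_pd > 0 and died.any():
            # attribute deaths from hernia states: premature with prob
            # p_pd / (p_pd + q(1 - p_pd)), mirroring the cohort bookkeeping
            q = params.life_table.q_at(age)
            from_hernia = died & ((state == NEW) | (state == REC))
            k = int(from_hernia.sum())
            if k:
                p_total = p_pd + q * (1.0 - p_pd)
                premature = rng.random(k) < (p_pd / p_total)
                yll = yll_value_per_death(t, settings, params.life_table, discounted=True)
                idx = np.flatnonzero(from_hernia)[premature]
                daly[idx] += yll
        state = nxt
    return MicrosimResult(
        mean_cost=float(cost.mean()),
        mean_daly=float(daly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
        se_daly=float(daly.std(ddof=1) / np.sqrt(n)),
        n=n,
    )


def generate_life_table(
    e40: float = 28.0,
    shape: float = 0.085,
    background: float = 0.0015,
    ages: np.ndarray | None = None,
) -> LifeTable:
    """Gompertz-style SYNTHETIC life table scaled to a target e(40).

    Annual mortality q(a) = background + A*exp(shape*(a-40)), with A solved
    so that remaining life expectancy at age 40 equals ``e40``.  The
    returned grid (default: age 18, then 20-85 in 5-year steps) carries a
    self-consistent ``ex`` column computed from the same q schedule.  This
    is a configuration artifact, not WHO data.
    """
    if e40 <= 0:
        raise ParameterError(f"e40 must be > 0, got {e40}")
    if e40 >= 60:
        raise ParameterError(
            f"e40={e40} requires near-zero mortality; remaining life expectancy "
            "would be unbounded under this parameterization"
        )
    if shape <= 0:
        raise ParameterError(f"shape must be > 0, got {shape}")
    omega = 111  # open-ended terminal age
    grid = np.arange(18, omega)

    def q_of(a_coef: float) -> np.ndarray:
        return np.clip(background + a_coef * np.exp(shape * (grid - 40.0)), 0.0, 0.7)

    def ex_at_40(a_coef: float) -> float:
        q = q_of(a_coef)
        i40 = int(np.flatnonzero(grid == 40)[0])
        surv = np.cumprod(1.0 - q[i40:])
        return float(surv.sum()) + 0.5

    lo, hi = 1e-8, 0.5
    if ex_at_40(lo) < e40:
        raise ParameterError(f"target e40={e40} unattainable even at minimal mortality")
    a_coef = brentq(lambda a: ex_at_40(a) - e40, lo, hi, xtol=1e-12)
    q = q_of(a_coef)

    # remaining life expectancy at every integer age, from the same schedule
    ex = np.empty_like(q)
    for i in range(len(grid)):
        surv = np.cumprod(1.0 - q[i:])
        ex[i] = surv.sum() + 0.5

    if ages is None:
        ages = np.concatenate([[18], np.arange(20, 86, 5)])
    idx = np.searchsorted(grid, ages)
    table = pd.DataFrame({"age": ages, "q": q[idx], "ex": ex[idx]})
    return LifeTable(table)
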