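"""Model inputs for the Sierra Leone inguinal hernia repair economic evaluation.

This module owns every symbol the model consumes: cohort settings (starting
age, horizon, discount rate, half-cycle correction), per-provider strategy
parameters (procedure cost, recurrence and contralateral risks, complication
rates), the IPQ-score-to-disability-weight mapping, the pre-/post-operative
pain distributions, the premature-death risk for untreated hernia, a
background-mortality life table, and the willingness-to-pay thresholds.

All probabilities are stored internally as fractions; percent conventions
appear only in reports.  ``default_parameters()`` returns the shipped
base-case configuration; ``load_parameters()`` reads a YAML file with the
same structure, filling any absent key with the default.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterError",
    "ModelSettings",
    "StrategyParams",
    "DisabilityWeights",
    "PainDistribution",
    "PrematureDeathInputs",
    "LifeTable",
    "ThresholdSet",
    "ParameterSet",
    "premature_death_risk",
    "ipq_to_dw",
    "default_parameters",
    "default_life_table",
    "load_parameters",
]

COMPLICATIONS = (
    "excessive_pain",
    "impaired_wound_healing",
    "wound_infection",
    "hematoma_reoperation",
)

PAIN_BANDS = ("none", "mild", "moderate", "severe")

#: IPQ score -> pain band.  Band 1 carries no pain; the GBD-derived weights
#: start at IPQ 2, so score 1 maps to a zero disability weight.
IPQ_BANDS = {1: "none", 2: "mild", 3: "mild", 4: "moderate", 5: "moderate", 6: "severe", 7: "severe"}


class ParameterError(ValueError):
    """A model input failed validation; the message names the offending field."""


def _check_prob(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
    return float(value)


def _check_nonneg(value: float, name: str) -> float:
    if value < 0:
        raise ParameterError(f"{name} must be non-negative, got {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# Settings and strategy inputs
# ---------------------------------------------------------------------------

@dataclass
class ModelSettings:
    """Cohort simulation settings.

    starting_age
        Age of the cohort at model entry, years (base case 40).
    horizon
        Number of annual cycles simulated (base case 10).
    cycle_length
        Fixed at one year.
    discount_rate
        Annual discount rate applied to costs and health outcomes (0.03).
    half_cycle_correction
        When True, state membership during a cycle counts deaths as half a
        cycle and is valued at the mid-cycle discount factor.
    yll_convention
        ``horizon_capped``: premature deaths lose the remaining (discounted)
        years inside the model horizon.  ``full_remaining_LE_discounted``:
        they lose the full discounted remaining life expectancy from the
        life table.
    discount_timing
        ``auto`` ties timing to the half-cycle correction (mid when on, end
        when off); ``start``/``mid``/``end`` force a convention.
    """

    starting_age: int = 40
    horizon: int = 10
    cycle_length: float = 1.0
    discount_rate: float = 0.03
    half_cycle_correction: bool = True
    yll_convention: Literal["full_remaining_LE_discounted", "horizon_capped"] = "horizon_capped"
    discount_timing: Literal["auto", "start", "mid", "end"] = "auto"

    def validate(self) -> "ModelSettings":
        if self.horizon <= 0:
            raise ParameterError(f"settings.horizon must be > 0, got {self.horizon}")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ParameterError(
                f"settings.discount_rate must be in [0, 1), got {self.discount_rate}"
            )
        if self.starting_age < 18:
            raise ParameterError(f"settings.starting_age must be >= 18, got {self.starting_age}")
        if self.cycle_length != 1.0:
            raise ParameterError("settings.cycle_length is fixed at 1 year")
        if self.yll_convention not in ("full_remaining_LE_discounted", "horizon_capped"):
            raise ParameterError(f"settings.yll_convention unknown: {self.yll_convention!r}")
        if self.discount_timing not in ("auto", "start", "mid", "end"):
            raise ParameterError(f"settings.discount_timing unknown: {self.discount_timing!r}")
        return self

    @property
    def state_timing(self) -> str:
        """Effective discount timing for state-membership accruals."""
        if self.discount_timing != "auto":
            return self.discount_timing
        return "mid" if self.half_cycle_correction else "end"


@dataclass
class StrategyParams:
    """Per-provider treatment strategy.

    ``provider`` is one of AC (associate clinician), MD (non-specialist
    medical doctor) or NONE (no repair).  Costs are 2023 USD per procedure;
    risks are annual probabilities.  Complication rates/unit costs feed the
    expected complication cost added to every procedure (unit costs default
    to zero: the Table 1 procedure costs are treated as all-inclusive).
    """

    provider: Literal["AC", "MD", "NONE"]
    cost_per_procedure: float = 0.0
    p_recurrence: float = 0.0
    p_contralateral: float = 0.0
    complication_rates: dict[str, float] = field(default_factory=dict)
    complication_unit_costs: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "StrategyParams":
        if self.provider not in ("AC", "MD", "NONE"):
            raise ParameterError(f"strategy.provider unknown: {self.provider!r}")
        _check_nonneg(self.cost_per_procedure, f"strategies.{self.provider}.cost_per_procedure")
        _check_prob(self.p_recurrence, f"strategies.{self.provider}.p_recurrence")
        _check_prob(self.p_contralateral, f"strategies.{self.provider}.p_contralateral")
        for name, rate in self.complication_rates.items():
            _check_prob(rate, f"strategies.{self.provider}.complication_rates.{name}")
        for name, cost in self.complication_unit_costs.items():
            _check_nonneg(cost, f"strategies.{self.provider}.complication_unit_costs.{name}")
        if self.provider == "NONE":
            if self.cost_per_procedure != 0 or self.p_recurrence != 0:
                raise ParameterError("strategies.NONE must have zero cost and no recurrence")
        return self

    @property
    def treated(self) -> bool:
        return self.provider != "NONE"


@dataclass
class DisabilityWeights:
    """GBD-style disability weights for the four IPQ pain bands."""

    none: float = 0.0
    mild: float = 0.0110
    moderate: float = 0.1140
    severe: float = 0.3240

    def validate(self) -> "DisabilityWeights":
        vals = [self.none, self.mild, self.moderate, self.severe]
        for name, v in zip(PAIN_BANDS, vals):
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"disability_weights.{name} must be in [0, 1], got {v}")
        if not (self.none <= self.mild <= self.moderate <= self.severe):
            raise ParameterError(
                "disability_weights must be non-decreasing: none <= mild <= moderate <= severe"
            )
        return self

    def for_band(self, band: str) -> float:
        try:
            return getattr(self, band)
        except AttributeError:
            raise ParameterError(f"unknown pain band {band!r}") from None


@dataclass
class PainDistribution:
    """Fractions of the cohort in each pain band; must sum to one."""

    none: float = 0.0
    mild: float = 0.0
    moderate: float = 0.0
    severe: float = 0.0

    def validate(self, label: str = "pain_distribution") -> "PainDistribution":
        total = 0.0
        for band in PAIN_BANDS:
            v = getattr(self, band)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{label}.{band} must be in [0, 1], got {v}")
            total += v
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"{label} fractions must sum to 1 (got {total!r})")
        return self

    def mean_dw(self, dws: DisabilityWeights) -> float:
        """Expected disability weight under this band mix."""
        return sum(getattr(self, b) * dws.for_band(b) for b in PAIN_BANDS)

    @classmethod
    def degenerate(cls, band: str) -> "PainDistribution":
        if band not in PAIN_BANDS:
            raise ParameterError(f"unknown pain band {band!r}")
        return cls(**{band: 1.0})


def premature_death_risk(p_complication: float, p_mortality: float) -> float:
    """Annual risk of early death without surgery.

    The product of the annual risk of an acute complication (incarceration or
    strangulation) in an untreated hernia and the case fatality of such a
    complication without timely surgical care.
    """
    _check_prob(p_complication, "p_complication")
    _check_prob(p_mortality, "p_mortality")
    return p_complication * p_mortality


@dataclass
class PrematureDeathInputs:
    """Inputs behind the untreated-hernia premature death risk."""

    p_complication: float = 0.0056
    p_mortality_given_complication: float = 0.20

    def validate(self) -> "PrematureDeathInputs":
        _check_prob(self.p_complication, "premature_death.p_complication")
        _check_prob(
            self.p_mortality_given_complication,
            "premature_death.p_mortality_given_complication",
        )
        return self

    @property
    def p_premature_death(self) -> float:
        return premature_death_risk(self.p_complication, self.p_mortality_given_complication)


def ipq_to_dw(ipq_score: int, dws: DisabilityWeights) -> float:
    """Banded lookup of the disability weight for an IPQ score (1-7)."""
    if int(ipq_score) != ipq_score or not (1 <= int(ipq_score) <= 7):
        raise ParameterError(f"ipq_score must be an integer in 1..7, got {ipq_score!r}")
    return dws.for_band(IPQ_BANDS[int(ipq_score)])


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

class LifeTable:
    """Age-indexed background mortality and remaining life expectancy.

    Wraps a DataFrame with columns ``age`` (years), ``q`` (annual mortality
    probability) and ``ex`` (remaining life expectancy, years).  Lookups at
    intermediate ages interpolate linearly; ages outside the grid clamp to
    the nearest row.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age", "q", "ex"}
        missing = required - set(table.columns)
        if missing:
            raise ParameterError(f"life_table missing columns: {sorted(missing)}")
        df = table[["age", "q", "ex"]].astype(float).sort_values("age").reset_index(drop=True)
        if df["age"].duplicated().any():
            raise ParameterError("life_table ages must be unique")
        if ((df["q"] < 0) | (df["q"] > 1)).any():
            raise ParameterError("life_table.q values must be probabilities in [0, 1]")
        if not (np.diff(df["ex"].to_numpy()) < 0).all():
            raise ParameterError("life_table.ex must be strictly decreasing in age")
        self._df = df
        self._ages = df["age"].to_numpy()
        self._q = df["q"].to_numpy()
        self._ex = df["ex"].to_numpy()

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def q_at(self, age: float) -> float:
        return float(np.interp(age, self._ages, self._q))

    def ex_at(self, age: float) -> float:
        return float(np.interp(age, self._ages, self._ex))

    def covers(self, low: float, high: float) -> bool:
        return self._ages[0] <= low and high <= self._ages[-1]

    def require_coverage(self, low: float, high: float) -> None:
        if not self.covers(low, high):
            raise ParameterError(
                f"life_table covers ages {self._ages[0]:.0f}-{self._ages[-1]:.0f}, "
                f"but {low:.0f}-{high:.0f} required"
            )

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)

    def to_records(self) -> list[dict]:
        return self._df.to_dict("records")


def default_life_table() -> LifeTable:
    """Bundled SYNTHETIC life-table stub.

    A Gompertz-parameterized grid (5-year steps, ages 18-85) scaled so that
    remaining life expectancy at age 40 is about 28 years — plausible for
    Sierra Leone adult males.  It is a configuration artifact standing in
    for WHO country life tables (which are not redistributed here) and is
    replaceable by any user-supplied table in the same CSV schema.
    """
    from .synthetic import generate_life_table  # local import avoids a cycle

    return generate_life_table(e40=28.0)


# ---------------------------------------------------------------------------
# Thresholds and the full parameter set
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSet:
    """Cost-effectiveness thresholds: GDP per capita and 3x GDP WTP."""

    gdp_per_capita: float = 476.0

    def validate(self) -> "ThresholdSet":
        _check_nonneg(self.gdp_per_capita, "thresholds.gdp_per_capita")
        return self

    @property
    def wtp(self) -> float:
        return 3.0 * self.gdp_per_capita


# Shipped base-case pre-operative pain mix.  Calibrated once (see
# cea.calibrate_pre_op_pain_mix) so that the untreated cohort accrues 0.75
# DALYs over the default 10-year horizon; a mild/moderate mix with implied
# mean disability weight ~0.085.  Overridable in configuration.
DEFAULT_PRE_OP_PAIN = {
    "none": 0.0,
    "mild": 0.2803705594999197,
    "moderate": 0.7196294405000803,
    "severe": 0.0,
}

#: Post-operative default: pain resolved (chronic-pain fraction configurable).
DEFAULT_POST_OP_PAIN = {"none": 1.0, "mild": 0.0, "moderate": 0.0, "severe": 0.0}


@dataclass
class ParameterSet:
    """Complete, validated model configuration."""

    settings: ModelSettings
    strategies: dict[str, StrategyParams]
    disability_weights: DisabilityWeights
    pre_op_pain: PainDistribution
    post_op_pain: PainDistribution
    premature_death: PrematureDeathInputs
    life_table: LifeTable
    thresholds: ThresholdSet
    budget_impact: Optional[object] = None  # budget_impact.BIASettings when present

    def validate(self) -> "ParameterSet":
        self.settings.validate()
        for name, strat in self.strategies.items():
            if name != strat.provider:
                raise ParameterError(f"strategies.{name}: provider field says {strat.provider!r}")
            strat.validate()
        for required in ("AC", "MD", "NONE"):
            if required not in self.strategies:
                raise ParameterError(f"strategies.{required} is required")
        self.disability_weights.validate()
        self.pre_op_pain.validate("pain_distributions.pre_op")
        self.post_op_pain.validate("pain_distributions.post_op")
        self.premature_death.validate()
        self.thresholds.validate()
        self.life_table.require_coverage(
            self.settings.starting_age, self.settings.starting_age + self.settings.horizon
        )
        if self.budget_impact is not None:
            self.budget_impact.validate()
        return self

    @property
    def p_premature_death(self) -> float:
        return self.premature_death.p_premature_death

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "settings": dataclasses.asdict(self.settings),
            "strategies": {k: dataclasses.asdict(v) for k, v in self.strategies.items()},
            "disability_weights": dataclasses.asdict(self.disability_weights),
            "pain_distributions": {
                "pre_op": dataclasses.asdict(self.pre_op_pain),
                "post_op": dataclasses.asdict(self.post_op_pain),
            },
            "premature_death": dataclasses.asdict(self.premature_death),
            "life_table": self.life_table.to_records(),
            "thresholds": dataclasses.asdict(self.thresholds),
        }
        if self.budget_impact is not None:
            d["budget_impact"] = dataclasses.asdict(self.budget_impact)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        base = default_parameters()
        data = dict(data or {})

        def merged(section: str, default_dict: dict) -> dict:
            user = data.get(section) or {}
            if not isinstance(user, dict):
                raise ParameterError(f"config section {section!r} must be a mapping")
            out = dict(default_dict)
            out.update(user)
            return out

        settings = ModelSettings(**merged("settings", dataclasses.asdict(base.settings)))
        strategies = {}
        strat_cfg = data.get("strategies") or {}
        for name, strat_default in base.strategies.items():
            out = dict(dataclasses.asdict(strat_default))
            out.update(strat_cfg.get(name) or {})
            strategies[name] = StrategyParams(**out)
        dws_cfg = merged("disability_weights", dataclasses.asdict(base.disability_weights))
        dws = DisabilityWeights(**dws_cfg)
        pain_cfg = data.get("pain_distributions") or {}
        pre = dict(dataclasses.asdict(base.pre_op_pain))
        pre.update(pain_cfg.get("pre_op") or {})
        post = dict(dataclasses.asdict(base.post_op_pain))
        post.update(pain_cfg.get("post_op") or {})
        premature = PrematureDeathInputs(
            **merged("premature_death", dataclasses.asdict(base.premature_death))
        )
        lt_cfg = data.get("life_table")
        if lt_cfg is None:
            life_table = base.life_table
        elif isinstance(lt_cfg, dict) and "csv" in lt_cfg:
            life_table = LifeTable.from_csv(lt_cfg["csv"])
        else:
            life_table = LifeTable(pd.DataFrame(lt_cfg))
        thresholds = ThresholdSet(**merged("thresholds", dataclasses.asdict(base.thresholds)))
        bia = None
        if "budget_impact" in data or base.budget_impact is not None:
            from .budget_impact import BIASettings

            bia_cfg = dataclasses.asdict(base.budget_impact) if base.budget_impact else {}
            bia_cfg.update(data.get("budget_impact") or {})
            bia = BIASettings(**bia_cfg)
        ps = cls(
            settings=settings,
            strategies=strategies,
            disability_weights=dws,
            pre_op_pain=PainDistribution(**pre),
            post_op_pain=PainDistribution(**post),
            premature_death=premature,
            life_table=life_table,
            thresholds=thresholds,
            budget_impact=bia,
        )
        return ps.validate()

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_parameters(with_budget_impact: bool = True) -> ParameterSet:
    """The shipped base-case parameterization (2023 USD, fractions)."""
    strategies = {
        "AC": StrategyParams(
            provider="AC",
            cost_per_procedure=149.0,
            p_recurrence=0.0092,
            p_contralateral=0.0038,
            complication_rates={
                "excessive_pain": 0.0522,
                "impaired_wound_healing": 0.0696,
                "wound_infection": 0.0522,
                "hematoma_reoperation": 0.0174,
            },
            complication_unit_costs={c: 0.0 for c in COMPLICATIONS},
        ),
        "MD": StrategyParams(
            provider="MD",
            cost_per_procedure=163.0,
            p_recurrence=0.0686,
            p_contralateral=0.0038,
            complication_rates={
                "excessive_pain": 0.0439,
                "impaired_wound_healing": 0.0789,
                "wound_infection": 0.0351,
                "hematoma_reoperation": 0.0088,
            },
            complication_unit_costs={c: 0.0 for c in COMPLICATIONS},
        ),
        "NONE": StrategyParams(provider="NONE"),
    }
    bia = None
    if with_budget_impact:
        from .budget_impact import BIASettings

        bia = BIASettings()
    ps = ParameterSet(
        settings=ModelSettings(),
        strategies=strategies,
        disability_weights=DisabilityWeights(),
        pre_op_pain=PainDistribution(**DEFAULT_PRE_OP_PAIN),
        post_op_pain=PainDistribution(**DEFAULT_POST_OP_PAIN),
        premature_death=PrematureDeathInputs(),
        life_table=default_life_table(),
        thresholds=ThresholdSet(),
        budget_impact=bia,
    )
    return ps.validate()


def load_parameters(config_path) -> ParameterSet:
    """Load and validate a YAML configuration, defaulting absent keys."""
    with open(config_path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError(f"config root must be a mapping, got {type(data).__name__}")
    return ParameterSet.from_dict(data)
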