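"""Procedure, complication and cohort-level cost accounting (2023 USD).

The Table 1 per-procedure costs (AC 149, MD 163) are treated as
all-inclusive by default, so complication unit costs ship as zero; users
with bottom-up line items (materials, medicines, human resources, capital,
overhead) can assemble a per-procedure cost with ``bottom_up_cost`` and
price complications explicitly.  Cohort costs charge the initial procedure
(plus expected complication cost) at time zero undiscounted, and re-repairs
of recurrent or contralateral hernias at the strategy's procedure cost in
the cycle they occur, discounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import COMPLICATIONS, ModelSettings, ParameterError, StrategyParams

__all__ = [
    "CATEGORIES",
    "CONSUMABLE_CATEGORIES",
    "ResourceItem",
    "bottom_up_cost",
    "expected_complication_cost",
    "CostResult",
    "cohort_cost",
    "attach_costs",
    "resource_items_from_csv",
]

CATEGORIES = ("materials", "medicines", "human_resources", "capital", "overhead")
#: Categories consumed per procedure; the rest are annual costs allocated by
#: share and divided by annual procedure volume.
CONSUMABLE_CATEGORIES = ("materials", "medicines")


@dataclass
class ResourceItem:
    """One bottom-up costing line.

    ``quantity`` is per procedure for consumables and the annual amount for
    human resources, capital and overhead; ``allocation_share`` is the
    fraction of an annual cost attributed to surgical care.
    """

    name: str
    category: str
    quantity: float
    unit_cost: float
    allocation_share: float = 1.0

    def validate(self) -> "ResourceItem":
        if self.category not in CATEGORIES:
            raise ParameterError(f"resource item {self.name!r}: unknown category {self.category!r}")
        if self.quantity < 0:
            raise ParameterError(f"resource item {self.name!r}: quantity must be >= 0")
        if self.unit_cost < 0:
            raise ParameterError(f"resource item {self.name!r}: unit_cost must be >= 0")
        if not (0.0 <= self.allocation_share <= 1.0):
            raise ParameterError(f"resource item {self.name!r}: allocation_share must be in [0, 1]")
        return self


def resource_items_from_csv(path) -> list[ResourceItem]:
    df = pd.read_csv(path)
    return [
        ResourceItem(
            name=row["name"],
            category=row["category"],
            quantity=float(row["quantity"]),
            unit_cost=float(row["unit_cost"]),
            allocation_share=float(row.get("allocation_share", 1.0)),
        ).validate()
        for _, row in df.iterrows()
    ]


def bottom_up_cost(items: list[ResourceItem], annual_volume: float) -> float:
    """Per-procedure cost from bottom-up line items.

    Consumables contribute quantity x unit cost per procedure; annualized
    human-resource, capital and overhead costs contribute their allocated
    share divided by the annual procedure volume.
    """
    if annual_volume <= 0:
        raise ParameterError(f"annual_volume must be > 0 to allocate annual costs, got {annual_volume}")
    per_procedure = 0.0
    annual = 0.0
    for item in items:
        item.validate()
        if item.category in CONSUMABLE_CATEGORIES:
            per_procedure += item.quantity * item.unit_cost
        else:
            annual += item.quantity * item.unit_cost * item.allocation_share
    return per_procedure + annual / annual_volume


def expected_complication_cost(strategy: StrategyParams) -> float:
    """Expected per-procedure cost of treating post-operative complications."""
    total = 0.0
    for name in set(COMPLICATIONS) | set(strategy.complication_rates):
        rate = strategy.complication_rates.get(name, 0.0)
        unit = strategy.complication_unit_costs.get(name, 0.0)
        total += rate * unit
    return total


@dataclass
class CostResult:
    """Discounted cohort cost decomposition (per model entrant, 2023 USD)."""

    initial_procedure: float
    complication: float
    re_repair_disc: float

    @property
    def total(self) -> float:
        return self.initial_procedure + self.complication + self.re_repair_disc


def cohort_cost(trace, strategy: StrategyParams, settings: ModelSettings) -> CostResult:
    """Total discounted cost of a cohort trace under its strategy."""
    if not strategy.treated:
        return CostResult(0.0, 0.0, 0.0)
    comp = expected_complication_cost(strategy)
    per_event = strategy.cost_per_procedure + comp
    df = trace.df
    initial = float(df["initial_repairs"].sum())  # charged at time 0, undiscounted
    re_repair = float((df["re_repairs"] * per_event * df["disc_event"]).sum())
    return CostResult(
        initial_procedure=initial * strategy.cost_per_procedure,
        complication=initial * comp,
        re_repair_disc=re_repair,
    )


def attach_costs(trace, strategy: StrategyParams, settings: ModelSettings) -> CostResult:
    """Fill the trace's per-cycle cost columns and return the totals."""
    df = trace.df
    comp = expected_complication_cost(strategy)
    per_event = strategy.cost_per_procedure + comp
    # initial procedure at time zero (discount factor 1), re-repairs in-cycle
    df["cost_undisc"] = (df["initial_repairs"] + df["re_repairs"]) * per_event
    df["cost_disc"] = df["initial_repairs"] * per_event + df["re_repairs"] * per_event * df[
        "disc_event"
    ]
    return cohort_cost(trace, strategy, settings)
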