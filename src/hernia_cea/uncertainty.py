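"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-evaluates the full cost-effectiveness comparison with one
parameter at its low and high bound (±20% of base for most inputs; discount
rate 0%/3.5% and starting age 30/50 as published) and ranks parameters by
the width of the resulting ICER interval (tornado diagram ordering).

PSA draws all uncertain inputs jointly — disability weights and risk
probabilities from beta distributions matched to the published mean/SD by
the method of moments, with a truncated-normal fallback when the SD is
incompatible with a beta at that mean — and re-runs the model per draw.
Cost-effectiveness acceptability uses net monetary benefit membership
(lambda x DALYs averted - incremental cost >= 0), which avoids ICER sign
ambiguities off the northeast quadrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cea import compare_strategies, evaluate_strategy
from .parameters import ParameterError, ParameterSet

__all__ = [
    "DSASpec",
    "TornadoEntry",
    "resolve_path",
    "set_path",
    "default_dsa_specs",
    "one_way_dsa",
    "PSADistribution",
    "default_psa_distributions",
    "sample_psa",
    "PSAOutput",
    "run_psa",
    "ceac",
    "DEFAULT_PSA_SEED",
]

#: Recorded in every PSA output so runs are reproducible by default.
DEFAULT_PSA_SEED = 20240

Comparison = tuple[str, str]  # (comparator, strategy)


# ---------------------------------------------------------------------------
# Parameter paths
# ---------------------------------------------------------------------------

def _walk(params: ParameterSet, path: str):
    obj = params
    parts = path.split(".")
    for part in parts[:-1]:
        if isinstance(obj, dict):
            if part not in obj:
                raise ParameterError(f"cannot resolve {path!r}: no key {part!r}")
            obj = obj[part]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ParameterError(f"cannot resolve {path!r}: no attribute {part!r}")
    return obj, parts[-1]


def resolve_path(params: ParameterSet, path: str) -> float:
    """Read a scalar parameter by dotted path, e.g. 'strategies.AC.cost_per_procedure'."""
    obj, leaf = _walk(params, path)
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ParameterError(f"cannot resolve {path!r}: no key {leaf!r}")
        return obj[leaf]
    if not hasattr(obj, leaf):
        raise ParameterError(f"cannot resolve {path!r}: no attribute {leaf!r}")
    return getattr(obj, leaf)


def set_path(params: ParameterSet, path: str, value) -> None:
    obj, leaf = _walk(params, path)
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ParameterError(f"cannot resolve {path!r}: no key {leaf!r}")
        obj[leaf] = value
    elif hasattr(obj, leaf):
        cur = getattr(obj, leaf)
        if isinstance(cur, bool):
            value = bool(value)
        elif isinstance(cur, int) and not isinstance(value, bool):
            # settings like starting_age stay integers
            value = int(value) if float(value).is_integer() else float(value)
        setattr(obj, leaf, value)
    else:
        raise ParameterError(f"cannot resolve {path!r}: no attribute {leaf!r}")


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class DSASpec:
    """One tornado bar: a parameter (or group varied jointly) with bounds."""

    paths: Sequence[str] | str
    base: float
    low: float
    high: float
    label: Optional[str] = None

    def __post_init__(self):
        if isinstance(self.paths, str):
            self.paths = (self.paths,)
        else:
            self.paths = tuple(self.paths)
        if not (self.low <= self.base <= self.high):
            raise ParameterError(
                f"DSA spec {self.label or self.paths}: need low <= base <= high, "
                f"got {self.low}, {self.base}, {self.high}"
            )
        if self.label is None:
            self.label = self.paths[0]


@dataclass
class TornadoEntry:
    label: str
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def default_dsa_specs(params: ParameterSet, comparison: Comparison) -> list[DSASpec]:
    """The published one-way DSA parameter set, restricted to a comparison.

    ±20% bounds for costs, disability weights and risks (using the printed
    rounded bounds), discount rate 0-3.5%, starting age 30-50, and the
    half-cycle correction toggled off at the low end.
    """
    comparator, strategy = comparison
    active = {comparator, strategy}
    specs = [
        DSASpec("settings.discount_rate", 0.03, 0.0, 0.035, label="discount_rate"),
        DSASpec("settings.starting_age", 40, 30, 50, label="starting_age"),
        DSASpec("settings.half_cycle_correction", 1, 0, 1, label="half_cycle_correction"),
        DSASpec("disability_weights.mild", 0.0110, 0.0088, 0.0132, label="dw_mild"),
        DSASpec("disability_weights.moderate", 0.1140, 0.0912, 0.1368, label="dw_moderate"),
        DSASpec("disability_weights.severe", 0.3240, 0.2592, 0.3888, label="dw_severe"),
        DSASpec(
            ("strategies.AC.p_contralateral", "strategies.MD.p_contralateral"),
            0.0038,
            0.0030,
            0.0046,
            label="p_contralateral",
        ),
        DSASpec(
            "premature_death.p_complication",
            0.0055,
            0.0045,
            0.0065,
            label="p_premature_death",  # varied via its dominant factor: 0.11% (0.09-0.13%)
        ),
    ]
    if "AC" in active:
        specs.append(
            DSASpec("strategies.AC.cost_per_procedure", 149, 120, 179, label="cost_per_procedure_AC")
        )
        specs.append(
            DSASpec("strategies.AC.p_recurrence", 0.0092, 0.0073, 0.0110, label="p_recurrence_AC")
        )
    if "MD" in active:
        specs.append(
            DSASpec("strategies.MD.cost_per_procedure", 163, 130, 195, label="cost_per_procedure_MD")
        )
        specs.append(
            DSASpec("strategies.MD.p_recurrence", 0.0686, 0.0549, 0.082, label="p_recurrence_MD")
        )
    return specs


def _icer_value(params: ParameterSet, comparison: Comparison) -> float:
    """Signed cost-per-DALY-averted ratio for tornado purposes.

    Dominance corresponds to a negative ratio (cost saving per DALY gained);
    the raw ratio keeps the tornado well defined across quadrants.
    """
    a = evaluate_strategy(params, comparison[0])
    b = evaluate_strategy(params, comparison[1])
    res = compare_strategies(a, b, params.thresholds)
    if res.dalys_averted == 0:
        raise ParameterError(f"comparison {comparison}: zero DALYs averted, ICER undefined")
    return res.incremental_cost / res.dalys_averted


def one_way_dsa(
    params: ParameterSet,
    specs: Optional[Iterable[DSASpec]] = None,
    comparison: Comparison = ("NONE", "AC"),
) -> list[TornadoEntry]:
    """One-way DSA over the specs, sorted by descending ICER span."""
    if specs is None:
        specs = default_dsa_specs(params, comparison)
    entries = []
    for spec in specs:
        values = {}
        for bound_name, bound in (("low", spec.low), ("high", spec.high)):
            p = params.copy()
            for path in spec.paths:
                resolve_path(p, path)  # raises early on a bad path
                set_path(p, path, bound)
            values[bound_name] = _icer_value(p, comparison)
        entries.append(TornadoEntry(label=spec.label, icer_low=values["low"], icer_high=values["high"]))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry], base_icer: float) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.label,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "span": e.span,
                "base_icer": base_icer,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSADistribution:
    """A sampled input: mean/SD with a distribution family on its support."""

    path: str
    mean: float
    sd: float
    family: str = "beta"
    label: Optional[str] = None

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError(f"PSA {self.path}: sd must be >= 0")
        if self.family not in ("beta", "gamma", "normal"):
            raise ParameterError(f"PSA {self.path}: unknown family {self.family!r}")
        if self.family == "beta" and not (0.0 < self.mean < 1.0) and self.sd > 0:
            raise ParameterError(f"PSA {self.path}: beta requires mean in (0, 1)")
        if self.label is None:
            self.label = self.path.rsplit(".", 1)[-1]

    def sampler(self, rng: np.random.Generator):
        m, s = self.mean, self.sd
        if s == 0:
            return lambda n: np.full(n, m)
        if self.family == "beta":
            var = s * s
            if var >= m * (1 - m):
                warnings.warn(
                    f"PSA {self.path}: sd {s} incompatible with beta at mean {m}; "
                    "falling back to a [0,1]-truncated normal",
                    stacklevel=2,
                )
                a, b = (0 - m) / s, (1 - m) / s
                return lambda n: stats.truncnorm.rvs(a, b, loc=m, scale=s, size=n, random_state=rng)
            nu = m * (1 - m) / var - 1.0
            alpha, beta = m * nu, (1 - m) * nu
            return lambda n: rng.beta(alpha, beta, size=n)
        if self.family == "gamma":
            shape = (m / s) ** 2
            scale = s * s / m
            return lambda n: rng.gamma(shape, scale, size=n)
        return lambda n: rng.normal(m, s, size=n)


def default_psa_distributions() -> list[PSADistribution]:
    """Published PSA inputs: disability weights and recurrence/contralateral risks.

    Procedure costs are excluded (the published PSA block lists only weights
    and risks).  Risk SDs are read on the fraction scale.
    """
    return [
        PSADistribution("disability_weights.mild", 0.0114, 0.0040, "beta", label="dw_mild"),
        PSADistribution("disability_weights.moderate", 0.1140, 0.0200, "beta", label="dw_moderate"),
        PSADistribution("disability_weights.severe", 0.3240, 0.0550, "beta", label="dw_severe"),
        PSADistribution("strategies.AC.p_recurrence", 0.0092, 0.0001, "beta", label="p_recurrence_AC"),
        PSADistribution("strategies.MD.p_recurrence", 0.0686, 0.0001, "beta", label="p_recurrence_MD"),
        PSADistribution(
            ("strategies.AC.p_contralateral"), 0.0038, 0.0007, "beta", label="p_contralateral_AC"
        ),
        PSADistribution(
            ("strategies.MD.p_contralateral"), 0.0038, 0.0007, "beta", label="p_contralateral_MD"
        ),
    ]


def sample_psa(
    dists: list[PSADistribution], n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """n joint independent draws of all PSA inputs, one column per path."""
    if n <= 0:
        raise ParameterError(f"PSA draw count must be > 0, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = {}
    for dist in dists:
        draws = np.asarray(dist.sampler(rng)(n), dtype=float)
        if dist.family == "beta":
            draws = np.clip(draws, 0.0, 1.0)
        data[dist.path] = draws
    return pd.DataFrame(data)


@dataclass
class PSAOutput:
    """Per-draw incremental results for each comparison, plus the draws."""

    n: int
    seed: int
    parameter_draws: pd.DataFrame
    increments: dict = field(default_factory=dict)  # comparison -> DataFrame(d_cost, d_daly)

    def frame(self) -> pd.DataFrame:
        df = self.parameter_draws.copy()
        df.insert(0, "draw", np.arange(1, self.n + 1))
        for (a, b), inc in self.increments.items():
            df[f"d_cost_{b}_vs_{a}"] = inc["d_cost"].to_numpy()
            df[f"d_daly_{b}_vs_{a}"] = inc["d_daly"].to_numpy()
        return df


def run_psa(
    params: ParameterSet,
    dists: Optional[list[PSADistribution]] = None,
    n: int = 1000,
    seed: int = DEFAULT_PSA_SEED,
    comparisons: Sequence[Comparison] = (("NONE", "MD"), ("NONE", "AC"), ("MD", "AC")),
) -> PSAOutput:
    """Re-evaluate the full model for each joint parameter draw."""
    if dists is None:
        dists = default_psa_distributions()
    draws = sample_psa(dists, n, seed)
    names = sorted({name for comp in comparisons for name in comp})
    records = {comp: {"d_cost": [], "d_daly": []} for comp in comparisons}
    for i in range(n):
        p = params.copy()
        for path in draws.columns:
            set_path(p, path, float(draws.iloc[i][path]))
        outs = {name: evaluate_strategy(p, name) for name in names}
        for a, b in comparisons:
            records[(a, b)]["d_cost"].append(outs[b].total_cost - outs[a].total_cost)
            records[(a, b)]["d_daly"].append(outs[a].total_daly - outs[b].total_daly)
    increments = {comp: pd.DataFrame(rec) for comp, rec in records.items()}
    return PSAOutput(n=n, seed=seed, parameter_draws=draws, increments=increments)


def ceac(
    psa: PSAOutput, thresholds: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve per comparison.

    For each willingness-to-pay lambda, the fraction of draws with
    non-negative net monetary benefit lambda*dDALY - dCost.
    """
    if not psa.increments:
        raise ParameterError("PSA output holds no comparisons")
    if thresholds is None:
        thresholds = np.arange(0.0, 1501.0, 10.0)
    rows = []
    for lam in thresholds:
        row = {"threshold": float(lam)}
        for (a, b), inc in psa.increments.items():
            nmb = lam * inc["d_daly"].to_numpy() - inc["d_cost"].to_numpy()
            row[f"p_ce_{b}_vs_{a}"] = float(np.mean(nmb >= 0))
        rows.append(row)
    return pd.DataFrame(rows)


def ceac_crossings(curve: pd.DataFrame, column: str) -> dict:
    """Summary statistics of one CEAC column: 50% crossing and first lambda at 1."""
    thr = curve["threshold"].to_numpy()
    p = curve[column].to_numpy()
    at_half = thr[p >= 0.5]
    at_one = thr[p >= 1.0]
    return {
        "threshold_p50": float(at_half[0]) if at_half.size else None,
        "threshold_p100": float(at_one[0]) if at_one.size else None,
    }
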