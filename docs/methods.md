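# Methods

This note records the model as implemented: its structure, the conventions
chosen where the source material leaves room, the calibrated defaults, and
what the synthetic-data machinery does and does not establish.

## Cohort model

Four exclusive health states — new hernia, recurrent hernia, repaired,
dead — simulated in annual cycles over a 10-year horizon from age 40.
Transition probabilities combine per-cycle risks as independent events:
the union 1−(1−p₁)(1−p₂) is allocated proportionally to the raw rates, so
ordering is irrelevant and rows are stochastic by construction.

**Treatment pathway.** The cohort enters 100% in *new hernia*. Under a
repair strategy the procedure is delivered during cycle 1: the cohort
spends that cycle at pre-operative disability (trial outcomes were
measured one year after surgery) and its survivors occupy *repaired* from
cycle 2. Because the trial's recurrence endpoint is "within one year of
surgery", recurrence and contralateral risks apply from the treatment
cycle onward — the first recurrent cohort presents at the start of cycle 2.
A recurrent or contralateral hernia spends one cycle at pre-operative
disability and is re-repaired in that cycle at the strategy's procedure
cost; re-repairs carry the same downstream risks as the initial repair.

**Untreated pathway.** Hernia states carry background mortality plus the
premature-death risk of an unrepaired hernia, p = P(acute complication) ×
P(death | complication) = 0.0056 × 0.20 ≈ 0.11%/yr. Treated cohorts carry
no premature-death risk in any cycle: the quantity is defined for patients
*without* surgery, and the published repaired-state DALY totals are
reproduced only as pure morbidity.

**Two deliberate accounting conventions.**

1. *Background deaths accrue no YLL.* Only premature hernia deaths add
   years of life lost. Without this convention the untreated DALY totals
   are unreachable; it also keeps the comparison clean, since background
   mortality is identical across strategies.
2. *Half-cycle correction.* State membership during a cycle is the
   start-of-cycle occupancy; deaths within a cycle count half a cycle of
   membership; state accruals are valued at the mid-cycle discount factor
   (1+r)^−(t−0.5). One-off events differ: the initial procedure is charged
   at time zero undiscounted, and re-repairs are valued at the start of the
   cycle in which the recurrent hernia presents (it arose during the
   preceding year). With the correction off, everything is valued at cycle
   end. The timing is configurable (`settings.discount_timing`); the
   published source does not state its placement, and the alternatives
   differ by under 2% on every reported quantity.

## DALY accounting

DALY = YLD + YLL, discounted at 3%/yr.

**YLD** accrues per cycle as occupancy-weighted mean disability weight ×
person-time. Hernia states use the pre-operative pain mix; *repaired* uses
the post-operative mix (default: pain fully resolved, DW 0, with a
configurable chronic-mild fraction). IPQ scores map to GBD-derived weights
by band — 1 → 0, 2–3 → 0.0110, 4–5 → 0.1140, 6–7 → 0.3240; score 1 (no
pain) maps to zero weight, the only consistent extension of bands that
start at IPQ 2. The lifetime formulation (DW × remaining life expectancy)
is exposed as `yld_literal` for comparison but is not used by the model:
it contradicts a 10-year horizon.

**YLL** values each premature death by `settings.yll_convention`:

* `horizon_capped` (default): the discounted remaining cycles inside the
  horizon (plus the half cycle not lived when the correction is on);
* `full_remaining_LE_discounted`: the discounted full remaining life
  expectancy at the age of death, from the life table.

The default is horizon-capped because the full-LE convention adds ≈0.26
discounted DALYs to every untreated total, pushing the moderate-pain
subgroup far above its published value; under the capped convention both
subgroup totals land within a few percent. Both are one switch apart.

YLL is linear in the premature-death risk at the operating scale
(deviation <1% below ≈0.4%/yr); above that, depletion of the at-risk pool
bends it measurably below the tangent (≈2.7% at 1%/yr).

## Calibrated defaults

Three quantities are not printed in the source material and ship as
calibrated or back-derived defaults, all overridable:

* **Base-case pre-operative pain mix** — mild 0.2804 / moderate 0.7196
  (implied mean DW ≈ 0.085), solved with `cea.calibrate_pre_op_pain_mix`
  so the untreated cohort accrues exactly 0.75 DALYs over the horizon.
* **Adult male population** 2,566,837 — the published prevalent pool
  220,748 divided by the 8.6% prevalence; growth 2.1%/yr yields a 10-year
  backlog of ≈581,000 (published: ≈578,000).
* **Provider productivity** 27.5 repairs/provider-year — solved from
  2,100 providers clearing that backlog in 10 years. The budget-impact
  sensitivity raises it to 5 repairs per working day (1,300/yr).

The procedure costs 149/163 USD are treated as all-inclusive, so
complication unit costs default to zero; users with bottom-up line items
(materials, medicines, human resources, capital, overhead) can assemble
per-procedure costs with `costing.bottom_up_cost` and price the four
complication categories explicitly.

## Life table

The bundled life table is a **synthetic stub**: Gompertz mortality
q(a) = 0.0015 + A·e^{0.085(a−40)} with A solved so that remaining life
expectancy at 40 is 28 years (plausible for Sierra Leone adult males),
tabulated on a 5-year grid from 18 to 85 with a self-consistent `ex`
column. It stands in for WHO country life tables, which are not
redistributed here; any table with columns `age,q,ex` can replace it.
Because the default YLL convention is horizon-capped, model results are
insensitive to the stub's `ex` column (it matters only under the full-LE
convention).

## Sensitivity analyses

**One-way DSA** re-evaluates the chosen comparison with one parameter (or
a jointly varied group, e.g. the contralateral risk shared by both
providers) at its low/high bound — ±20% for costs, weights and risks
(published rounded bounds), discount 0–3.5%, starting age 30–50, and the
half-cycle correction toggled — and ranks parameters by the width of the
ICER interval. The signed ratio ΔCost/ΔDALY keeps dominated/dominant
comparisons well defined in the tornado.

**PSA** draws disability weights and risk probabilities from beta
distributions matched to the published mean/SD by the method of moments
(truncated-normal fallback, with a warning, when the SD is incompatible
with a beta at that mean). Costs are not sampled — the published PSA block
lists only weights and risks. Risk SDs are read on the fraction scale
(0.0001 on p = 0.0092): a percent-scale reading would make them vanish.
Draws are independent across parameters (no correlation structure is
reported); the printed "PSA" column is treated as an illustrative draw,
not a constraint. The acceptability curve uses net-monetary-benefit
membership, λ·ΔDALY − ΔCost ≥ 0, avoiding ICER sign ambiguity; both the
50%-probability crossing and the first λ with probability 1 are reported,
since "becomes cost-effective at λ" can denote either. The default seed
(20240) is recorded in every output.

## Budget impact

Undiscounted, 2024–2033. The status-quo projection grows the population
geometrically, adds incidence (1,250/100k/yr) and subtracts baseline
repairs (470/100k/yr). The open-budget scenario delivers the total need —
initial pool plus all incident cases — in equal annual volumes through the
task-sharing expansion (which supersedes the baseline rate), training all
providers up front (annual volume ÷ productivity, rounded up) at USD
2,000 each and renovating one facility per three providers at USD 12,000.
The capped scenario funds expansion repairs at the all-in unit cost
(share-weighted procedure cost 0.68×163 + 0.32×149 = 158.52, plus
training and renovation prorated over a provider's horizon output,
≈ USD 180 in total) until the cumulative ceiling is exhausted; the
fraction addressed is funded repairs over the total 10-year need.
Incidence and repair rates are interpreted per 100,000 *adult males* (the
prevalence base). Mass balance — cumulative repairs + final backlog =
initial pool + cumulative incidence — holds exactly whenever the backlog
is not clipped at zero.

An optional `complication_cost_per_repair` (default 0) represents
post-operative complication treatment in the budget; the published
supplementary line items behind it are not available, so the "remove
complication costs" sensitivity is a no-op under the defaults and is
reported as such.

## Synthetic data and what green tests establish

`generate_trial_cohort` emulates the source trial at the individual level:
provider allocation, banded IPQ scores (uniform within band), Bernoulli
recurrence and independent Bernoulli complications at the configured
rates. It does not simulate randomization blocks, loss to follow-up, or
any correlation between complications. `estimate_parameters` closes the
loop with ML proportions and Wilson 95% intervals.

`microsim_oracle` is an independent check on the cohort engine: n
individuals pushed through the same transition matrices with random
transitions and identical valuation conventions. Agreement within 3
Monte-Carlo standard errors at n = 100,000 establishes that the cohort
engine's expectations are implemented correctly — not that the model is
clinically right. Disability in the microsimulation is valued at the mean
weight of the pain mix, matching the cohort expectation while reducing
variance.

## Numerical choices

* Probabilities are stored as fractions; reports echo percent conventions.
* ICER boundaries classify upward to the less favourable class (an ICER
  exactly at GDP per capita is "cost-effective", not "very").
* Equal costs and DALYs classify as "indifferent"; cheaper-and-better is
  "dominant"; costlier-and-worse "dominated"; no ICER is reported in
  those branches.
* Report rounding mirrors the published tables (whole USD, DALYs to 2
  d.p., whole-USD ICERs); all internal arithmetic is full precision.
* Life-table lookups interpolate linearly and clamp outside the grid;
  coverage of the simulated age range is validated up front.
* The pain-mix and life-table calibrations use Brent root-finding with
  tolerances far below reporting precision.

## Known limitations

* The four-state structure has no memory: recurrence risk does not depend
  on the number of prior repairs, and no tunnel states are modelled.
* Recurrence and mortality risks are age-constant (only background q
  varies with age).
* A healthcare-system cost perspective: no out-of-pocket or productivity
  costs.
* The PSA omits cost uncertainty and parameter correlation.
* The budget projection has no queueing or waiting-time structure; the
  published USD 108M (Results) vs USD 104M (Discussion) discrepancy for
  the open-budget scenario is noted — the mechanical costing here yields
  ≈USD 105M.
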