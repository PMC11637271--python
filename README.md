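# hernia-cea

Cost-effectiveness and budget-impact modelling of task-shared inguinal
hernia repair in Sierra Leone.

Sierra Leone has one of the world's largest backlogs of untreated inguinal
hernia in adult men, and far too few specialist surgeons to clear it. The
policy question this package addresses: is elective open mesh repair
delivered by **associate clinicians (ACs)** and **non-specialist medical
doctors (MDs)** — task-sharing — good value for money compared with leaving
hernias untreated, and what would it cost the country to clear the backlog
over a decade?

It is aimed at health economists and global-surgery researchers who want a
tested, scriptable version of this analysis: every input is a plain
configuration value, every convention is explicit, and every published
headline number is recomputed by code rather than copied.

## The model

A four-state Markov cohort model with annual cycles over a 10-year horizon
(cohort entry at age 40, discount rate 3%, half-cycle correction):

```
new hernia ──repair──▶ repaired ──recurrence──▶ recurrent hernia ──re-repair──▶ repaired
     │                    │                          │
     └────────────────────┴──────── death ◀──────────┘
```

* Untreated hernia states face background mortality *q(age)* plus a
  premature-death risk *p* = P(complication) × P(death | complication)
  = 0.0056 × 0.20 ≈ 0.11%/yr.
* Health outcome: DALYs = YLD + YLL. YLD accrues per cycle as the
  occupancy-weighted disability weight (DW), with Inguinal Pain
  Questionnaire (IPQ) scores mapped to GBD weights — mild (IPQ 2–3)
  0.0110, moderate (4–5) 0.1140, severe (6–7) 0.3240. YLL accrues only
  from premature hernia deaths.
* Costs (2023 USD, health-system perspective): procedure cost 149 (AC) /
  163 (MD) at time zero, plus discounted re-repairs of recurrent (0.92%/yr
  AC, 6.86%/yr MD) and contralateral (0.38%/yr) hernias.
* ICER = ΔCost / ΔDALYs averted, classified against the WHO convention
  (very cost-effective below 1× GDP per capita = USD 476, cost-effective
  below 3×).
* Uncertainty: one-way deterministic sensitivity analysis (±20%, tornado
  ranking) and probabilistic sensitivity analysis (beta-distributed weights
  and risks, method of moments; CE plane and acceptability curves).
* Budget impact: undiscounted 2024–2033 projection of the national backlog
  (220,748 prevalent cases, incidence 1,250/100k/yr, 68/32 MD/AC mix) under
  open-budget clearance and cumulative budget ceilings, including provider
  training (USD 2,000/trainee) and facility renovation (USD 12,000 per
  3-provider facility).

Conventions, calibrated defaults and their rationale are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import hernia_cea as hc

params = hc.default_parameters()
report = hc.full_cea(params)
print(report.frame().to_string(index=False))
```

prints (costs in whole USD, DALYs to 2 d.p.):

```
   panel comparison  cost_comparator  cost_strategy  daly_comparator  daly_strategy  incremental_cost  dalys_averted      icer      classification
    base MD vs NONE                0            251             0.75           0.13               251           0.62       404 very_cost_effective
    base AC vs NONE                0            163             0.75           0.09               163           0.66       248 very_cost_effective
    base   AC vs MD              251            163             0.13           0.09               -88           0.04 Dominates            dominant
moderate MD vs NONE                0            251             0.99           0.17               251           0.82       307 very_cost_effective
moderate AC vs NONE                0            163             0.99           0.12               163           0.87       189 very_cost_effective
moderate   AC vs MD              251            163             0.17           0.12               -88           0.05 Dominates            dominant
  severe MD vs NONE                0            251             2.73           0.49               251           2.24       112 very_cost_effective
  severe AC vs NONE                0            163             2.73           0.35               163           2.38        69 very_cost_effective
  severe   AC vs MD              251            163             0.49           0.35               -88           0.14 Dominates            dominant
```

Reading the base-case rows: an untreated patient accrues 0.75 DALYs over
ten years; repair by an AC costs USD 163 in total and leaves 0.09 DALYs,
so the AC strategy buys a DALY averted for USD 248 — far below the USD 476
GDP-per-capita threshold. AC repair dominates MD repair (cheaper by USD 88
with slightly more health gain), driven by the much lower recurrence rate.
ICERs fall with pre-operative severity: the sicker the patient, the better
the value of surgery.

The budget-impact side:

```python
from hernia_cea import average_procedure_cost, open_budget_scenario

bia = params.budget_impact
proj = open_budget_scenario(bia, average_procedure_cost(bia, params.strategies))
print(round(proj.total_backlog), round(proj.cumulative_cost / 1e6, 1), proj.providers_trained)
# 581097 104.8 2114
```

i.e. clearing the ten-year backlog of ≈581,000 repairs costs ≈USD 105
million and requires ≈2,100 newly trained task-sharing providers.

The same analyses are available from the shell:

```bash
hernia-cea cea --out out/cea
hernia-cea dsa --out out/dsa --plots
hernia-cea psa --n 1000 --seed 20240 --out out/psa --plots
hernia-cea bia --scenario capped --ceiling 10e6 --out out/bia
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from the shipped
defaults — cohort model, subgroup analyses and budget projections — and
writes the headline quantities (strategy costs, ICERs, untreated DALY
totals, open-budget cost and backlog, capped-budget fractions) to a JSON
file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All reported values are computed at run time; nothing is hard-coded.
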