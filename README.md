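# psmcea — partitioned survival cost-effectiveness analysis

`psmcea` is a Python package for partitioned survival cost-effectiveness
modelling of oncology regimens, built around the comparison of the three
FDA-approved immunotherapy + chemotherapy combinations (dostarlimab,
pembrolizumab, durvalumab, each with carboplatin/paclitaxel) against
chemotherapy alone in advanced or recurrent endometrial cancer. It is aimed
at health-economics and outcomes researchers who want an open, tested,
scriptable alternative to closed-source decision-modelling software.

## The model

A partitioned survival model derives health-state occupancy directly from
the two trial survival curves instead of from transition probabilities. At
every time *t* over a 5-year horizon the cohort splits into three mutually
exclusive states:

```
PF(t) = PFS(t)            progression-free
PP(t) = OS(t) − PFS(t)    post-progression
D(t)  = 1 − OS(t)         dead
```

Effectiveness is measured primarily in **quality-adjusted progression-free
life-years saved (QA-PFLYS)** — the utility-weighted integral of PF(t) over
the horizon, with a probability-weighted utility penalty during the
grade ≥3 toxicity window — and secondarily in QALYs, which add the
utility-weighted post-progression time. Costs accrue per administration:
six induction cycles every 3 weeks followed by maintenance dosing at each
drug's own interval and stopping rule (2-year cap for pembrolizumab, up to
3 years for dostarlimab, until progression for durvalumab), with the first
three cycles always delivered and later doses weighted by the probability
of being progression-free at the dose time. Strategies are compared by the
incremental cost-effectiveness ratio

```
ICER = ΔCost / ΔQA-PFLYS        ($/QA-PFLYS, 2024 USD)
```

against a willingness-to-pay threshold of $100,000/QA-PFLYS. On top of the
deterministic engine the package provides:

* **threshold analysis** — the per-administration immunotherapy price at
  which a strategy's ICER equals the threshold, in closed form (drug cost
  is exactly linear in the price) and verified by root-finding;
* **one-way / tornado analysis** — ICER ranges as each parameter moves
  between bounds, sorted by width;
* **probabilistic sensitivity analysis** — Monte-Carlo parameter draws
  (gamma costs, beta probabilities/utilities, lognormal treatment-effect
  perturbations) summarized as cost-effectiveness acceptability curves;
* **a synthetic trial generator** — per-patient progression and death times
  with proportional-hazards effects and administrative censoring, turned
  into Kaplan–Meier step curves, so the whole pipeline runs without any
  external data.

## Worked example

```python
import psmcea as m

scenario = m.build_scenario("dmmr")          # bundled dMMR scenario, seeded
result = m.run_pipeline(scenario)
cols = result.table[["incremental_cost", "incremental_effect", "icer"]]
print(cols.round({"incremental_cost": 0, "incremental_effect": 3, "icer": 0}))
```

```
           incremental_cost  incremental_effect      icer
strategy
TC                      NaN                 NaN       NaN
PEM-TC             332192.0               1.322  251303.0
DOS-TC-2y          366642.0               1.369  267817.0
DOS-TC-3y          478531.0               1.369  349547.0
DUO-TC-2y          214530.0               0.886  242111.0
DUO-TC-3y          266027.0               0.886  300228.0
```

Each row compares one strategy with chemotherapy alone (TC): pembrolizumab
adds about $332k and 1.3 QA-PFLYS, an ICER of ~$251k/QA-PFLYS — far above
the $100,000 threshold, and the cheapest of the three drugs per
quality-adjusted progression-free year gained among the 3-year/2-year-cap
variants (PEM < DUO-3y < DOS-3y). The break-even price:

```python
th = m.break_even_price(scenario, "PEM-TC")
print(round(th.break_even_price), round(th.decrease))
# 4869 7469
```

i.e. the pembrolizumab price per induction administration would have to
fall from $12,338 to ~$4,870 (a ~$7,470 cut) for the regimen to be
cost-effective at $100,000/QA-PFLYS under this scenario's curves.

The same analyses are available from the shell:

```bash
psmcea run --preset dmmr --out results/
psmcea threshold --preset dmmr --strategy PEM-TC
psmcea tornado --preset dmmr --strategy PEM-TC --out tornado.csv
psmcea psa --preset dmmr --n 1000 --seed 7 --out results/
psmcea simulate --preset dmmr --out scenario/     # curves + YAML to edit
```

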