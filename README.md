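# cltsce

Societal cost-effectiveness analysis of community-led total sanitation
(CLTS) interventions.

CLTS is a no-subsidy, demand-generation approach to ending open
defecation (OD): facilitators "trigger" rural communities to build and
use latrines. This package implements a retrospective societal
cost-effectiveness pipeline for four CLTS delivery variants evaluated
across five regions of Ethiopia and Ghana (conventional facilitation by
health extension workers or NGO staff, and pilot variants adding
teachers or trained community "natural leaders"), for analysts who want
to reproduce, stress-test, or extend that style of analysis on their own
survey and cost data.

## What it computes

The core statistic is the cost-effectiveness ratio

```
CE_i = Cost / Outcome_i,        i ∈ {stopped OD, gained usable latrine}
```

where *Cost* is the societal total — program costs (management,
training, facilitation) plus local costs (local-actor time, community
time, hired labor, latrine hardware), with unpaid time monetized at a
value-of-time wage rate — and *Outcome_i* is the number of households
stopping open defecation or gaining ownership of a usable latrine
(observed on survey day with stable flooring and not full). Around this
sit:

- **`synthetic`** — calibrated two-wave household-survey panels and cost
  ledgers, so the whole pipeline is testable without the (undeposited)
  raw data;
- **`outcomes`** — observation-validated classification (reported
  private latrines that are full, unstable, or unobservable count as
  OD), recall-based and conservative baseline estimation, and
  achieving-household counts;
- **`costing`** — bottom-up activity-based ledgers, time monetization,
  and region→country→study roll-ups (no discounting; two-year horizon);
- **`cea`** — CE ratios per household and per person, incremental
  cost-effectiveness ratios (ICER = Δcost/Δeffect) with dominance
  labels, and explicit flagged-undefined handling where an outcome
  worsened (a negative ratio is misleading, so it is suppressed with a
  note, mirroring the published tables);
- **`uncertainty`** — Monte Carlo probabilistic sensitivity analysis:
  ±30% uniform distributions on each cost category, normal distributions
  on outcome changes (SD defaulting to 50% of the point estimate where
  no empirical SD exists), percentile 95% CIs truncated at zero;
- **`pipeline` / `cli`** — configuration, CSV I/O, and end-to-end report
  bundles, with the published cost and outcome tables bundled as the
  regression fixture.

## Worked example

```python
from cltsce import datasets, total_cost, cost_effectiveness, per_person, icer, run_psa

ledgers = datasets.load_reference_ledgers()     # 15 published cost columns
outcomes = datasets.load_reference_outcomes()   # matching outcome counts

key = ("All CLTS interventions", "All regions")
cost = total_cost(ledgers[key])
ch = outcomes[key]
ce = per_person(
    cost_effectiveness(cost.total, ch.households_stopping_od, "stopped_od", *key),
    ch.n_people, ch.n_households,
)
hew, teacher = ("HEW CLTS", "Ethiopia"), ("Teacher CLTS", "Ethiopia")
res = icer(
    (total_cost(ledgers[hew]).total, outcomes[hew].households_stopping_od),
    (total_cost(ledgers[teacher]).total, outcomes[teacher].households_stopping_od),
)
psa = run_psa(ledgers[hew], outcomes[hew], n_draws=1000, seed=1)["stopped_od"]
```

prints (via the obvious f-strings):

```
total societal cost: $576,060 (program $460,105 + local $115,955)
cost per household stopping OD: $358.92
cost per person stopping OD:    $75.28
ICER (teacher-facilitated vs conventional): $105.17 per additional household stopping OD (more effective, more costly)
PSA 95% CI for the conventional Ethiopia arm: [106.37, 1,297.57] around $218.69
```

Read: across the full study population it cost society about $359 per
household (≈$75 per person) converted from open defecation. Switching
from the conventional Ethiopian delivery to the teacher-facilitated
pilot bought each *additional* converting household for about $105. The
wide Monte Carlo interval shows how sensitive the ratio is to cost and
effect-size uncertainty — intervals of the two Ethiopian arms overlap,
so the simulations cannot rank them.

The same analysis from a shell:

```sh
cltsce report --out report/            # bundled published tables
cltsce simulate --profile Oromia --n 2000 --seed 7 --out sim/
cltsce outcomes --survey sim/survey.csv --out sim/outcomes.csv
cltsce cea --ledgers sim/ledgers.csv --outcomes sim/outcomes.csv --out sim/ce.csv
```

`cltsce report` writes four CSVs (outcome, cost, CE, and PSA tables)
plus a log of suppressed cells — in the bundled data the two SNNP
columns, where sanitation outcomes worsened and the four negative
outcome counts make the CE ratios undefined.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full reference analysis from scratch — parses the bundled
cost and outcome tables, totals every column, recomputes all CE ratios
with their suppression flags, runs the 1000-draw Monte Carlo PSA, and
exercises the synthetic generator — and writes its results JSON.
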