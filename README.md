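# psorcea

Cost-utility analysis of sequenced biologic therapy for severe chronic
plaque psoriasis, from the Australian health-system perspective.

Australian PBS rules give biologic therapy a fixed rhythm: a 12-week
induction period and then 24-week maintenance periods, each ending in a
PASI75 review; failures switch to the next biologic line and, after three
failed lines, to best supportive care.  `psorcea` implements a Markov
cohort model of that process for the eight PBS-subsidised outpatient
biologics, evaluating each as a first-line choice over 96 weeks (eight
12-week cycles) and accruing 2020 AUD costs and QALYs with a half-cycle
(within-cycle) correction.  On top of the engine sit a dominance/frontier
classifier with incremental cost-utility ratios (ICUR = ΔC/ΔE, AUD per
QALY), a one-way (tornado) sensitivity analysis, and a probabilistic
sensitivity analysis with Beta/Gamma input distributions and
cost-effectiveness acceptability curves (CEAC, from net monetary benefit
NMB = λ·E − C over a willingness-to-pay grid).

It is written for health economists and dermatology researchers who want
to reproduce, stress or extend the published Australian comparison: every
input lives in one scenario document (drug pack prices, dose and dispense
calendars, PASI75 probabilities with CIs, monitoring/BSC costs,
utilities), and every analysis is a pure function of it.

## Worked example

```python
from psorcea import (builtin_base_case, build_strategies, evaluate_arm,
                     classify)

config = builtin_base_case()          # bundled AU 2020 scenario
results = [evaluate_arm(s, config) for s in build_strategies(config)]
report = classify(results)
print(report.frontier)
print(report.table[["strategy", "cost", "qaly", "status"]]
      .to_string(index=False, float_format=lambda v: f"{v:,.3f}"))
```

```
['tildrakizumab', 'secukinumab', 'risankizumab']
     strategy       cost  qaly             status
tildrakizumab 40,450.503 1.568           frontier
   adalimumab 42,451.467 1.554 strictly_dominated
  secukinumab 43,156.285 1.582           frontier
   ixekizumab 43,445.094 1.581 strictly_dominated
  ustekinumab 45,521.376 1.558 strictly_dominated
   etanercept 46,301.262 1.538 strictly_dominated
 risankizumab 50,003.724 1.587           frontier
   guselkumab 50,167.714 1.584 strictly_dominated
```

The tildrakizumab-first pathway is cheapest (AUD40,451 per patient,
1.568 QALYs over 96 weeks) and anchors the frontier; secukinumab and
risankizumab buy additional QALYs at roughly AUD190,000 and AUD500,000
per QALY respectively, and every other first-line choice is dominated.
The spread in QALYs across arms is small (1.54–1.59) — a signature of
treatment-sequencing models, where failures move onto the same effective
downstream drugs — so acquisition cost and dosing frequency drive the
ranking.

The same analyses are scripted under `analysis/` (each writes CSVs to
`results/`):

```sh
python analysis/01_base_case.py             # arm totals, frontier, trace
python analysis/02_one_way_sensitivity.py   # tornado table and ICUR ranges
python analysis/03_probabilistic_sensitivity.py   # PSA summary + CEAC
python analysis/04_alternative_sequencing.py      # swapped 2nd/3rd lines
```

or from the CLI: `psorcea basecase --out run/`, `psorcea owsa …`,
`psorcea psa --iterations 10000 --seed 1 …`, `psorcea generate …` (random
but valid scenarios for testing).  Every output directory contains a
`manifest.json` sufficient to reproduce the run exactly.

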