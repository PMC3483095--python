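# osteoburden

A prevalence-based burden-of-illness pipeline for osteoporosis-related
fractures, built for health economists and epidemiologists who work
with administrative-style hospital data. It covers the full chain run
in national cost-of-osteoporosis studies:

1. **Case identification** — fracture events in records aged 50+ via
   two definitions (most responsible diagnosis = fracture code, or
   secondary fracture code + a fracture-treatment intervention), with
   severe-trauma exclusion and site classification (hip, vertebral,
   wrist, humerus, multiple, other).
2. **Attribution** — hip/vertebral fractures attributed to osteoporosis
   at 100%; for other sites a sex-specific rate *X* solves
   `s·1 + (1−s)·X = target` where `s` is the hip+vertebral case share
   and the targets are 74.5% (men) / 90.4% (women), with an
   age-specific variant for women as a sensitivity.
3. **Costing** — patient-level resource-intensity-weight (RIW) costing
   of admissions, ER visits and day surgeries (RIW × $5,399.04 +
   length-of-stay-driven physician fees + diagnostics/procedures);
   net-transfer accounting into rehabilitation, continuing and
   long-term care; home care per recipient-week; blended physician
   fees; drug spend with private-claim scaling; human-capital indirect
   costs (productivity + caregiver wage losses).
4. **Extrapolation** — direct age–sex standardization from the observed
   provinces to the national population.
5. **Scenarios** — base case plus four sensitivity analyses
   (age-specific female attribution, osteoporosis-only admissions,
   prevalence-based long-term care, all-trauma inclusion), rendered as
   count/cost tables.

The real source databases are access-restricted, so a deterministic
synthetic generator (`osteoburden.synthetic_data`) produces record sets
with the same stratified structure, and the published national FY
2007/2008 estimates (`osteoburden.reference`) serve as benchmark
inputs. See `docs/methods.md` for the model, assumptions and
calibrations.

## Worked example

```python
import pandas as pd
from osteoburden import (
    GeneratorConfig, PipelineInputs, default_code_map, run_all_scenarios,
)
from osteoburden.synthetic_data import (
    generate_ambulatory_records, generate_discharge_records,
    generate_population_table,
)

cfg = GeneratorConfig(n_records=2000, seed=11)
inputs = PipelineInputs(
    discharge=generate_discharge_records(cfg),
    ambulatory=pd.concat(
        [generate_ambulatory_records(cfg, "ER"),
         generate_ambulatory_records(cfg, "day_surgery")],
        ignore_index=True,
    ),
    population=generate_population_table(cfg),
    code_map=default_code_map(),
)
results = run_all_scenarios(inputs)
base = results["base"]
print(f"national admissions (weighted): {base.counts['admissions_national']:,.0f}")
nt = base.net_transfers["rehabilitation"]
print(f"rehab net transfers: {nt.discharged_to:,.1f} - {nt.admitted_from:,.1f} -> {nt.net:,.1f}")
for name, res in results.items():
    print(f"{name:<24s} total ${res.breakdown.total:,.0f}")
```

prints

```
national admissions (weighted): 2,051
rehab net transfers: 250.8 - 8.9 -> 241.9
base                     total $605,902,343
rocq_attribution         total $605,953,030
add_op_only_admissions   total $668,675,054
ltc_prevalence           total $2,244,376,754
all_trauma               total $617,915,151
```

The admission count is the attribution-weighted number of fracture
hospitalizations extrapolated to the national population (weights are
fractional, so counts need not be integers); the rehabilitation line
shows discharges to rehab minus entrants from rehab, the net being the
osteoporosis-attributable placements that get costed. Scenario totals
behave as the model predicts: all-trauma and the osteoporosis-only
addition exceed the base case, and the long-term-care prevalence
scenario dominates everything because it costs the resident *stock*
for a full year rather than the incident net transfers. The physician
and drug components default to published national observed inputs, so
at this small synthetic scale they dominate the total; feed observed
inputs of matching scale for realistic shares.

Age bands are half-open decades [50, 60) … [90, ∞); a band label such
as `80-89` covers ages 80–89 inclusive.

A thin CLI wraps the same functions:

```bash
osteoburden generate --out data/ --seed 4 --n-records 5000
osteoburden identify --records data/discharge.csv --out cases.csv
osteoburden report --data data/ --out report/
```

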