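# ventgrowth

Growth phenotyping of microorganisms across a salinity × pH × temperature
factorial, from raw microplate optical-density time series to an
environmental-response classification.

The package is aimed at microbial ecologists and mycologists who measure
growth in microtiter plates — e.g. fungal isolates from extreme habitats
such as shallow hydrothermal vents — and need a reproducible pipeline for:

1. **Growth-curve modelling.** Each well's blank-subtracted OD630 series is
   fitted with the Richards generalized logistic model

   y(x) = a·[1 + (d − 1)·e^(−k(x − xc))]^(1/(1−d)),  d ≠ 1

   with upper asymptote *a*, rate constant *k* (1/day), shape *d* (> 1) and
   inflection time *xc* (days). At *d* = 2 this is the ordinary logistic.
   The per-well summary statistic is the **average normalized growth rate**

   rate = k / (2(d + 1))   [1/day],

   recorded as 0 for wells called as no-growth (flat traces, e.g. all wells
   at pH 1).

2. **Factorial statistics.** Growth-rate data from such assays are
   typically non-normal and heteroscedastic, so the pipeline uses the
   aligned rank transform (ART): per effect (pH, temperature, pH ×
   temperature) all other effects are stripped from the response via the
   cell-means decomposition before ranking, and a two-way fixed-effects
   ANOVA is run on each effect's ranks. Significant interactions are
   followed up with Kruskal-Wallis tests of each factor at each level of
   the other, Dunn's pairwise comparisons (tie-corrected), and compact
   letter displays. Analyses run separately per salinity stratum.

3. **Response classification.** Each organism's growth presence/absence
   over the grid is condensed into a profile and assigned, by explicit
   precedence rules, to one of three groups: `temperature_tolerant`
   (growth at 45 °C), `wide_range` (growth at 37 °C in both salinities, at
   pH 3, and in both salinities), or
   `salinity_dependent_temperature_sensitive` (the remainder).

A synthetic-plate simulator with known ground-truth Richards parameters
makes every stage testable without plate-reader data.

## Worked example

```python
import numpy as np
from ventgrowth import (RichardsParams, evaluate_richards, fit_richards,
                        normalized_growth_rate, group_counts)
from ventgrowth.datasets import load_vent_isolates

# simulate one noisy well and fit it back
truth = RichardsParams(a=0.8, k=0.5, d=3.0, xc=12.0)
days = np.arange(30, dtype=float)
rng = np.random.default_rng(1)
od = evaluate_richards(truth, days) + rng.normal(0, 0.02, 30)
fit = fit_richards(days, od)
p = fit.params
print(f"fitted: a={p.a:.3f}, k={p.k:.3f}, d={p.d:.3f}, xc={p.xc:.2f}")
print(f"normalized growth rate: {fit.rate:.4f} 1/day "
      f"(truth {normalized_growth_rate(truth):.4f})")
print(f"growth called: {fit.growth_flag} (R^2 = {fit.r_squared:.4f})")

counts = group_counts(load_vent_isolates())
print({k.value: v for k, v in counts.items()})
```

prints

```
fitted: a=0.793, k=0.524, d=3.217, xc=12.10
normalized growth rate: 0.0621 1/day (truth 0.0625)
growth called: True (R^2 = 0.9972)
{'wide_range': 4, 'salinity_dependent_temperature_sensitive': 5, 'temperature_tolerant': 1}
```

The fitted parameters sit close to the generating values despite the
measurement noise, and the rate statistic is recovered to within a few
percent. The final line classifies the packaged reference dataset of ten
hydrothermal-vent fungal isolates (growth occurrence over 2 salinities ×
5 pHs × 4 temperatures): four wide-range organisms, five restricted to
mild temperatures and often seawater, and one thermotolerant isolate —
the only one growing at 45 °C.

## Command line

```sh
ventgrowth simulate --organisms org_a,org_b --seed 1 --out plate.csv
ventgrowth fit      --plate plate.csv --out rates.csv
ventgrowth stats    --rates rates.csv --alpha 0.05 --adjust none --out stats/
ventgrowth classify --rates rates.csv --out groups.tsv
ventgrowth run      --config run.json       # all stages + report
```

The default simulated design is the full assay layout: 2 salinities
(0/30 ‰) × 5 pHs (1, 3, 5, 7, 9) × 4 temperatures (15/25/37/45 °C) ×
8 replicates = 320 inoculated wells per organism, read daily for 30 days,
plus one uninoculated control set per treatment.

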