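# judoba — in-contest body-acceleration profiling for judo

`judoba` is a Python toolkit for analysing the body accelerations (BA) of
judo athletes during contest, as recorded by a belt-worn triaxial
accelerometer. It is aimed at sports scientists and strength &
conditioning practitioners who want to characterise the mechanical
demands of the judo contest across the six sex × weight divisions
(male/female × light/middle/heavy), and at methodologists who want a
tested, seeded implementation of the statistical pipeline such a study
requires.

## What it computes

A contest is reduced from 3-second triaxial count epochs to:

- **Vector magnitude** per epoch, VM = √(x² + y² + z²), aggregated to
  counts per minute (a.u./cpm). The norm is applied per epoch *before*
  aggregation, matching device-level semantics.
- **Per-axis cpm** (vertical, mediolateral, anteroposterior) and each
  axis's percentage share of their sum.

The cells are then compared with a heteroscedasticity-tolerant battery:

- a **Johansen-type factorial test on 20% trimmed means** (the `t2way`
  procedure of the robust-ANOVA literature) for sex, weight, and
  sex × weight effects;
- **pairwise Yuen trimmed-mean contrasts** with family-wise error control
  via studentized-maximum-modulus critical values (`lincon` convention;
  Hochberg step-up available);
- **Rosenthal's r** effect sizes, r = |Z|/√N, with Z from the exact
  Wilcoxon-Mann-Whitney U distribution (full dynamic-programming
  enumeration for combined n ≤ 40);
- a **one-sample Pearson χ²** test of each division's axis shares
  against equal thirds (is any axis predominant?);
- a **Poisson Monte Carlo scenario table**: per axis and division, the
  median and 95%-interval bounds of Poisson(λ = mean axis share %), with
  occurrence probabilities (10,000 simulations per axis per division);
- the **ANOVA power analysis** that sizes such a study, via the
  noncentral F distribution (k·n·f² noncentrality).

Because raw contest recordings are not publicly distributable, the
package ships a first-class synthetic cohort generator calibrated to the
published per-cell summary statistics, so the whole pipeline runs
end-to-end from a seed.

## Worked example

```python
import pandas as pd
from judoba import (
    RobustFactorialANOVA, generate_cohort, load_cohort_config,
    summarize_trace, table2_cohort_path,
)
from judoba.accelio import summaries_frame

specs = load_cohort_config(table2_cohort_path())  # 6 cells, 16 athletes each
cohort = generate_cohort(specs, seed=7)
rows, meta = [], []
for profile, trace, physio in cohort:
    rows.append(summarize_trace(trace, physio))
    meta.append({"athlete_id": profile.athlete_id, "sex": profile.sex,
                 "weight_class": profile.weight_class})
df = summaries_frame(rows).merge(pd.DataFrame(meta), on="athlete_id")

res = RobustFactorialANOVA(df, "vm_cpm").fit()
print(res.summary())
```

Output (seed 7):

```
Robust factorial comparison: vm_cpm
  trimmed means (trim = 0.20), alpha = 0.05

  Cells (mean +/- sd [trimmed mean], n):
    FH: 7,342.4 +/- 281.8 [7,386.0] (n=16)
    FL: 7,971.5 +/- 310.6 [7,969.2] (n=16)
    FM: 7,986.4 +/- 371.7 [7,976.5] (n=16)
    MH: 7,454.5 +/- 376.9 [7,480.8] (n=16)
    ML: 9,198.9 +/- 749.2 [9,189.8] (n=16)
    MM: 8,518.2 +/- 846.0 [8,511.1] (n=16)

  Effects (Johansen-corrected):
               sex: Q =   26.560, p = 0.0000 *
            weight: Q =   97.265, p = 0.0000 *
     sex_by_weight: Q =   20.051, p = 0.0007 *

  Significant contrasts (family-wise p < 0.05):
    FH vs FL: p = 0.0004, r = 0.85 (great)
    FH vs FM: p = 0.0028, r = 0.80 (great)
    FH vs ML: p = 0.0001, r = 1.03 (great)
    FH vs MM: p = 0.0120, r = 0.73 (moderate)
    FL vs MH: p = 0.0131, r = 0.62 (moderate)
    FL vs ML: p = 0.0028, r = 0.83 (great)
    FM vs MH: p = 0.0308, r = 0.60 (moderate)
    FM vs ML: p = 0.0027, r = 0.83 (great)
    MH vs ML: p = 0.0001, r = 0.94 (great)
    MH vs MM: p = 0.0225, r = 0.64 (moderate)

  Gates: Bartlett p = 0.0000; robust battery used regardless of gate outcome.
```

The interaction p of 0.0007 says the weight-class gradient in BA differs
between the sexes: in this simulated cohort (as calibrated) light and
middle male weights produce distinctly higher BA than heavy males and
all female cells, while the female gradient is flatter. Rosenthal's r
marks the light-vs-heavy contrasts as moderate-to-great effects.

The same pipeline is available from the shell:

```bash
judoba all --seed 7 --out runs/demo          # bundled cohort, full report
judoba report --seed 7 --out runs/demo2 --mode empirical --n-sims 10000
```

which writes per-athlete epoch CSVs, a manifest, a per-cell summary
table, the robust comparison, the axis-uniformity tests, the scenario
table and formatted report tables, all bit-identical on rerun with the
same seed.

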