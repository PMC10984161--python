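# Methods

This note documents the models and procedures `judoba` implements, the
assumptions behind its synthetic cohorts, and the numerical choices a
user should know before trusting or extending the results.

## The measurement model

A contest recording is a sequence of 3-second epochs, each carrying
activity counts on three orthogonal axes (vertical, mediolateral,
anteroposterior). Counts are the device's dimensionless measure of
acceleration magnitude ("a.u."); everything downstream treats them as
given — no band-pass filtering or raw 30 Hz processing is modelled.

Per epoch, the vector magnitude is VM = √(x² + y² + z²). Because the
norm is nonlinear, VM is computed per epoch *before* any aggregation:
per-epoch VMs are summed within each contest minute and the per-minute
sums averaged to give vm_cpm. For a contest whose length divides into
whole minutes this equals the contest total scaled to one minute; the
minute-wise form is kept because it matches device-level "counts per
minute" semantics. Per-axis cpm is the linear analogue (axis totals ×
60/duration), and axis shares are each axis's cpm over the summed axis
cpm. Breaks are part of the contest record; cpm is computed over the
full duration with no break exclusion.

Group-level axis shares are means of per-athlete percentages
(mean-of-ratios), not percentages of cell-mean cpm: only per-athlete
percentages have a cell SD, which is what the summary tables report. The
ratio-of-means alternative can be computed from the per-axis cpm columns
if wanted.

## Synthetic cohort generator

Real contest recordings are not redistributable, so the generator
produces cohorts with the statistical structure the analysis assumes,
calibrated to per-cell summary targets (mean and SD of VM cpm, axis
shares, peak contest HR, post-contest blood lactate, Borg RPE, age). The
bundled `table2_cohort.yaml` encodes the published six-cell calibration
at n=16 per cell.

Per athlete:

1. **Schedule.** Effort bouts uniform on [20, 30] s (rounded to whole
   epochs) alternate with fixed 10 s breaks over a 300 s contest,
   truncated at the end. Mean bout length is therefore 25 s.
2. **Targets.** A per-contest VM target is drawn from a normal truncated
   at zero (cell mean/SD); axis shares are drawn logistic-normally
   around the cell shares (log-composition noise of scale sd/mean per
   axis), so each athlete's shares are positive and sum to 100 exactly.
3. **Epoch counts.** The target epoch count vector points along the
   athlete's shares; break epochs emit `break_intensity_fraction`
   (default 0.15) of the effort rate — breaks are recorded as quieter
   movement, not silence. Independent gamma noise (CV 0.25 by default)
   perturbs every epoch and axis: non-negative and right-skewed, as
   count data are.
4. **Exact rescaling.** The noisy float trace is rescaled by one global
   factor so its pre-rounding contest VM equals the athlete's drawn
   target, then rounded to integer counts. Without this step the
   convexity of the norm inflates E[VM] under multiplicative noise by a
   few percent at CV 0.25, which would bias every cell above target;
   with it, calibration error is limited to integer rounding (well under
   0.1% at realistic count magnitudes).
5. **Physiology.** HR, lactate, RPE and age are truncated-normal draws
   (HR and lactate at zero, RPE to the Borg 6–20 scale, age at 18).
   Predicted maximal HR is 208 − 0.7 × age, and %HRmax divides the drawn
   contest HR by it.

Randomness: each athlete gets a child stream
`SeedSequence(seed, spawn_key=(group_index, athlete_index))`, so cohorts
are bit-reproducible and enlarging one cell never changes another
athlete's draws.

**What the generator does not emulate.** Within-contest dynamics beyond
the effort/break alternation (no throw events, grip phases, or
autocorrelation between epochs), between-axis correlation at the epoch
level beyond the shared intensity, any VM-share or VM-physiology
correlation within cell, and measurement artefacts (device saturation,
belt movement). The published per-contest summaries constrain none of
these, so within-trace dispersion (`epoch_cv`, `break_intensity_fraction`)
is assumption, exposed in `ContestDesign`, and stated as such. Passing
calibration tests therefore shows the pipeline recovers the cell
structure it was pointed at — not that real contests have this
microstructure.

## Robust comparison battery

All six cells are compared with sex (2 levels) and weight class (3
levels) as factors, on 20% trimmed means. The trimming proportion is
the conventional default of the robust framework; it is exposed as a
parameter.

- **Trimmed mean / winsorized variance.** g = ⌊trim·n⌋ observations are
  removed (resp. clamped) from each tail; trim = 0 reduces both to the
  classical estimates. The squared standard error of a trimmed mean is
  d = (n−1)s²_w / (h(h−1)) with h = n − 2g.
- **Factorial test.** Johansen's heteroscedastic test of C·μₜ = 0 with
  V = diag(d): Q = (Cμ̂ₜ)'(CVC')⁻¹(Cμ̂ₜ), with the small-sample corrected
  critical value c + c/(2f)·A·(1 + 3c/(f+2)), f = rank(C),
  A = Σⱼ R²ⱼⱼ/(hⱼ−1), R = VC'(CVC')⁻¹C. The p-value is found by solving
  for the level at which Q equals its critical value (Brent's method on
  the level, rather than a fixed grid). Cells with zero winsorized
  spread and no mean contrast return Q = 0, p = 1 rather than a singular
  solve. Under balanced homoscedastic normality with trim = 0 the test
  tracks the classical two-way F-test closely (checked by simulation);
  its null interaction rejection rate at n=16/cell is within
  [0.03, 0.07] at nominal 0.05 (checked over 2,000 simulations).
- **Pairwise contrasts.** All 15 Yuen trimmed-mean comparisons with
  Welch-Satterthwaite df on winsorized variances. Family-wise control
  uses the studentized-maximum-modulus independence approximation:
  adjusted p = 1 − (2F_t(|T|; ν) − 1)^C for C = 15; Hochberg step-up is
  available as an option. Simulated family-wise error at the null is ≈
  0.05.
- **Effect sizes.** Rosenthal's r = |Z|/√N with Z the standard-normal
  quantile of the two-sided Wilcoxon-Mann-Whitney p, signed by
  direction. The U distribution is enumerated exactly by the standard
  dynamic-programming recurrence for tie-free combined samples up to
  N = 40 (the study's pairwise comparisons are N = 32); ties or larger
  samples fall back to the tie-corrected, continuity-corrected normal
  approximation, which differs from the exact p by < 0.01 at N ≥ 30 on
  continuous data. Magnitude labels: small r > 0.20, moderate r > 0.50,
  great r > 0.80.
- **Axis uniformity.** One-sample Pearson χ² of the three mean shares
  against equal thirds, with the percentages treated as observations on
  their own total (base 100) and df = 2. This is the reading that
  reproduces the published p-values from the published rounded shares
  for four of the six divisions; the remaining two (female light and
  middle) are not reproducible from rounded inputs — presumably
  unrounded means were used upstream — and are not asserted anywhere.
- **Gates.** Shapiro-Wilk per cell and Bartlett across cells are
  computed and reported (scipy implementations). They motivated the
  robust battery in the study design; here they are diagnostics only
  and never switch the analysis.

## Power analysis

The six groups are treated as a one-way fixed-effects ANOVA with k = 6.
For per-group size n, the F statistic has df (k−1, k(n−1)) and
noncentrality λ = k·n·f² at Cohen's effect size f; power is the
noncentral-F upper tail beyond the central-F critical value. The
required n is the smallest integer reaching the requested power — 16
per group at f = 0.40, α = 0.05, power = 0.85 (power 0.823 at n = 15,
0.852 at n = 16). A factorial decomposition of the power question is
possible but the one-way k=6 framing is the sizing convention
implemented.

## Scenario tables

For each axis in each division, the mean share percentage λ is taken as
the mean of a Poisson distribution over integer percentage values, and
three scenarios are reported: the 2.5%, 50% and 97.5% quantiles
("lower", "median", "upper"). Two modes:

- **exact** (default): quantiles from the exact Poisson CDF (smallest k
  with CDF ≥ q). Deterministic, reproducible, and the mode that matches
  the stable published cells.
- **empirical**: the same percentiles (inverted-CDF estimator) of
  10,000 seeded draws per axis per division (so a full 6 × 3 table is
  180,000 simulated contests). Empirical percentiles agree with exact
  quantiles except where a target percentile sits within roughly ±0.003
  of a CDF step, where they can flip by ±1 — the documented flip zone.

Each scenario value carries a probability of occurrence. The default
definition is the **point-mass frequency** — the fraction of simulated
contests landing exactly on that percentage — which at 10,000 draws
matches the exact Poisson pmf within Monte Carlo error. Lower/upper
tail masses and a ±1 band are selectable alternatives; every output is
labelled with the definition used. No published definition of these
probabilities is recoverable, so none is asserted against published
numbers.

Treating a percentage as a Poisson count is a modelling convention
(integer support, variance = mean); negative-binomial or Dirichlet
compositional alternatives are out of scope.

## Pipeline and determinism

`run_pipeline` executes simulate → summarize → compare → scenarios →
report as a DAG: each stage consumes only the run configuration or files
an earlier stage wrote. All randomness flows from the single run seed.
The run log records versions, the seed, and a SHA-256 hash of every
output file; wall-clock information goes to console logging only, so a
rerun with the same configuration is byte-identical. Stage failures
abort before any file of that stage is written; configuration errors
name the offending field.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to give stable verdicts:
2,000 replicates for the factorial type-I error (MC SE ≈ 0.5 points),
500 full generator-to-test replicates for interaction detection at the
study size, 200 athletes per cell for calibration recovery, and 10,000
draws wherever the scenario engine's defaults apply.

## Known limitations

- The within-contest noise model is an assumption; only cell-level
  summaries are calibrated.
- The SMM family-wise adjustment assumes independent contrasts; with 15
  overlapping pairwise comparisons it is mildly conservative.
- The exact WMW path requires tie-free data; integer-valued outcomes
  with ties use the normal approximation even at small N.
- Axis-share uniformity uses shares on a base of 100, so its χ² does not
  scale with the number of athletes — it is a descriptive test of the
  mean composition, not a per-athlete inference.
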