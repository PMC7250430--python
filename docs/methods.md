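# Methods

## Growth model

Each well's blank-subtracted OD630 series y(x) over days x is modelled by
the Richards generalized logistic curve

    y(x) = a · [1 + (d − 1) · e^(−k(x − xc))]^(1/(1−d)),   d ≠ 1

- **a** — upper asymptote (OD units): the plateau biomass proxy.
- **k** — rate constant (1/day).
- **d** — shape (dimensionless): where the inflection sits between 0 and
  a; d = 2 recovers the symmetric logistic, y(xc) = a·d^(1/(1−d)).
- **xc** — inflection time (days).

Only the sigmoid branch d > 1 is admitted. The 0 < d < 1 decaying branch
is rejected outright because the assay measures non-decreasing growth
curves; fitting it would let the optimizer explain noise with decay. The
d → 1 singularity is excluded by the lower bound on d.

The per-well summary handed to the statistics is the average normalized
growth rate, rate = k / (2(d + 1)) (1/day); it increases in k and
decreases in d, and is defined as 0 for no-growth wells.

### Fitting

Nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective) with bounds a ∈ (0, 2·max OD], k ∈ (0, 10], d ∈ (1, 20],
xc ∈ [first day − 5, last day + 5]. Initialization: a₀ = maximum of a
3-point moving average; xc₀ = first half-max crossing; k₀ = slope of
log OD over the early window between 5% and 80% of a₀ (clipped to
[0.05, 5]); d₀ = 2. Tolerances 1e-12; on noiseless synthetic wells the
parameters are recovered to relative error below 1e-4 (in practice,
machine precision).

Series whose maximum OD stays below the detection threshold are not sent
to the optimizer at all: no growth call is possible for them under the
threshold rule, so they are recorded directly as no-growth (rate 0,
converged = false). This also keeps a 320-well plate fit under a second.

### Growth call

A well is called as growing iff max OD ≥ `threshold_od` (default 0.05
absorbance) **and** the fit converged with R² ≥ `threshold_r2` (default
0.7); both comparisons are inclusive. The thresholds are free parameters:
no numeric criterion is standard for this assay, and both are exposed in
the configuration and CLI. Fits are per well; the 8 replicate rates per
treatment (not a pooled curve) feed the statistics, so between-replicate
variability is preserved.

## Blank subtraction

Growth signal = inoculated OD − per-day mean of the matching control
wells (same salinity, pH and temperature; the organism label is ignored
because one uninoculated control set per treatment serves all organisms).
The per-day mean (rather than a time-averaged constant) is an assumption;
it tracks medium drift such as slow evaporation. Negative values are
retained — clamping at zero would bias early-time noise upward and skew
the fit of small-signal wells. Subtraction is linear, so subtracting then
averaging replicates equals averaging then subtracting.

## Factorial statistics

Statistics are computed separately per (organism, salinity) stratum,
with pH and temperature as the two crossed factors. Shapiro-Wilk and
Brown-Forsythe (Levene on deviations from group medians) checks are
available for the rates; growth-rate data of this kind are usually
non-normal with heteroscedastic residuals, which motivates the
rank-based chain.

### Aligned rank transform

For effect E ∈ {A, B, A×B} the aligned response is

    y_aligned,E = (y − cell mean) + estimate(E)

with estimates from the unweighted cell-means decomposition: grand mean
μ = mean of cell means, main effects αᵢ = mean of row cell means − μ
(similarly βⱼ), interaction γᵢⱼ = cell mean − αᵢ − βⱼ − μ. Using means of
cell means (not raw marginal means) keeps the alignment exact for
unequal cell sizes. After aligning, responses are ranked (average ranks
for ties) and a standard two-way fixed-effects ANOVA is run on each
effect's rank column, reporting only the focal effect.

The alignment identity — every non-focal estimated effect of an aligned
column is zero — is asserted internally to 1e-9 on every input, so a
violation surfaces as an error rather than a silently wrong F statistic.
Under a null 4×4 layout with n = 8 per cell, the interaction test's
type-I error is within Monte-Carlo error of the nominal 5% (checked over
2000 simulated tables in the test suite).

The two-way ANOVA requires a balanced, fully crossed layout. Treatment
cells in which no replicate grows are excluded from the factorial
analysis (their zero rates carry no information about the factors, only
about the growth boundary); because dropping cells breaks the crossing,
the stratum is reduced to its largest fully crossed subgrid by greedily
removing the factor level with the most all-no-growth cells. Partially
growing cells keep their zero-rate replicates. If a factor falls below
two levels the stratum skips the two-way ANOVA (logged) and only the
one-way chain runs.

### One-way chain

At each level of one factor, the other factor's groups (cells with at
least one growing replicate) are compared by the tie-corrected
Kruskal-Wallis test, followed by Dunn's pairwise z tests,

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − ΣT/(12(N−1))]·(1/n_i + 1/n_j)),

ΣT = Σ(t³ − t) over tie groups, with two-sided normal p-values. The
default multiplicity adjustment is **none** — Dunn's z are reported raw —
with Bonferroni and Holm available; α = 0.05 throughout. The results are
rendered as compact letter displays (insert-and-absorb): two levels share
a letter iff they are not significantly different.

## Response classification

A condition counts as growth for an organism iff at least half of its
replicates are flagged (boundary inclusive). The profile is classified by
clause precedence:

1. **temperature_tolerant** — growth at 45 °C under any condition.
2. **wide_range** — growth at 37 °C in *both* salinities, growth at pH 3
   under some condition, and growth in both salinities.
3. **salinity_dependent_temperature_sensitive** — otherwise.

Clause 1 dominates because thermotolerance is the rarest and most
diagnostic trait. Clause 2 requires the 37 °C test in both salinities:
among the packaged ten reference isolates, every wide-range organism
grows at 37 °C in fresh and in sea water, whereas the salinity-dependent
organisms reach 37 °C (if at all) only in seawater — a single-salinity
test would misplace organisms whose warm growth is itself
salinity-dependent. Classification uses presence/absence only; rate
magnitudes are deliberately not weighed, since the group concept is about
growth *ranges*. All clause thresholds are configurable via
`ClassifierRules`.

The packaged `vent_isolates.csv` encodes growth occurrence for ten
hydrothermal-vent fungal isolates over the full grid. Descriptive
accounts of growth ranges hedge some cells ("growth generally occurred
at..."); where a cell was not stated explicitly the encoding follows the
organism's summarized range. Classifying the fixture yields 4 wide-range,
5 salinity-dependent/temperature-sensitive and 1 temperature-tolerant
isolate.

## Synthetic plates

The simulator emulates: daily readings for 30 days (day 0 included); the
2 × 5 × 4 × 8 layout (320 inoculated wells per organism) plus one control
set per treatment; sigmoidal growth with additive Gaussian noise
truncated at zero (absorbance is non-negative); flat no-growth wells;
no growth at pH 1 for any organism and growth at 45 °C for exactly one.
Noise sd defaults to 0.01 absorbance and the control baseline to 0.08 —
values typical of a 630 nm microplate assay in weak malt-extract medium;
neither is derived from data, and both are free parameters.

A single master seed drives a per-well substream keyed by
`crc32(well_id)`, so simulations are reproducible bit-for-bit and
subsetting a design leaves the remaining wells' noise unchanged.

Not modelled (hence not demonstrated by passing tests): evaporation and
edge effects, optical saturation at high biomass, well-position
systematics, spore-inoculum dose effects, and non-sigmoid kinetics such
as diauxie or death phases. Real plates also produce occasional
contaminated or skipped wells; the parser enforces completeness instead.

## Problem sizes in the test and acceptance runs

Calibration of the ART interaction test uses 2000 null tables (4×4,
n = 8); the Monte-Carlo standard error at 5% is ≈0.5 percentage points,
comfortably inside the ±2-point acceptance band. Noisy-recovery checks
use 100 seeds × 8 replicate wells at noise sd 0.02. Nonparametric oracle
checks enumerate group-size compositions with total n ≤ 12 and all
significance patterns for up to 4 levels. These sizes give stable checks
at interactive runtimes.

## Known limitations

- ART here is the two-factor fixed-effects variant; mixed or repeated-
  measures designs are out of scope.
- Kruskal-Wallis p-values are asymptotic (chi-square), not exact
  permutation values; with n = 8 per group this is adequate.
- The Richards fit assumes homoscedastic residuals within a well; OD
  noise that grows with signal would call for weighted least squares.
- The classifier's clauses are an operationalization of descriptive
  groupings; applying them to organisms far outside the tested grid
  (e.g. psychrophiles) would need re-tuned thresholds.
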