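# Methods

## The two classification arms

**Direct BMI-for-age arm** (`growthscreen.bmi`). BMI is computed as
weight(kg)/height(m)² — height is converted from the recorded centimeters
to meters; the unrounded BMI is carried internally and rounded half-up to
1 dp only for presentation. The overweight threshold at a child's sex and
completed month of age is the inverse LMS transform at z = +1 of the
BMI-for-age reference. The comparison is a strict `>` ("exceeding" the
cutoff): a BMI exactly on the threshold is healthy. Completed months (the
floor of exact age) is the row index throughout, so a 10-year-2-month-old
is looked up at 122 months, never interpolated.

**Simplified screening arm** (`growthscreen.screening`). The table builder
evaluates, for every half-year age row a ∈ {5.0, 5.5, …, 19.0} years
(month row 12a) and every percentile column p ∈ {1, 3, 5, 15, 25, 50, 75,
85, 95, 97, 99}: the column height h_p from the height-for-age LMS
percentile (rendered to 0.1 cm), and the cell weight
`BMI₊₁SD × (h_p/100)²` rounded half-up to 0.1 kg. Cell weights are
computed from the *rendered* column heights so that the exported table is
self-consistent: a child standing exactly on a printed column height meets
the cell weight that was derived from that printed height, and the only
gap between the two arms on-grid is the 0.1 kg cell rounding band. The
11 columns and the rendering convention are configurable defaults, since
published instruments of this kind differ in which percentile set and
rendering they print; a ±0.2 kg tolerance is used whenever package-built
cells are compared to published ones.

Lookup: a child's age matches one row when completed-months/12 sits on
the half-year grid, else the two bracketing rows; a height matches one
column when it equals a printed height, else the two bracketing columns
(1–4 cells in total). Heights outside a row's column span clamp to the
nearest edge column and the lookup is flagged. The decision rule is
**weight ≥ minimum matched cell → unhealthy**. Two deliberate asymmetries
with the direct arm, both consequences of how such instruments are used:
the minimum over bracketing cells can only lower the threshold, and the
comparison is ≥ at the printed cell ("placed within the grid") where the
BMI arm is strictly >. Together these make the instrument's errors
one-sided: on any cohort whose references increase monotonically with
age, every child flagged by the BMI arm is flagged by the tables (the
2×2 c-cell is structurally 0 and positive percent agreement is 100%),
while borderline-healthy children may be over-called (the b-cell). The
only exceptions possible are clamped lookups (height below the 1st or
above the 99th percentile column) and weights inside the 0.1 kg rounding
band, both rare and both recorded in the per-child audit detail.

## LMS numerics

- `|L| < 1e-7` switches to the exact log-normal branch (`z = ln(x/M)/S`),
  avoiding catastrophic cancellation in `((x/M)^L − 1)/(L·S)`; the two
  branches agree to < 1e-6 across the switch.
- The inverse transform rejects arguments with `1 + L·S·z ≤ 0` (outside
  the Box–Cox support) as domain errors rather than returning complex or
  clipped values. Forward/inverse round-trips hold to 1e-9 relative.
- Percentiles map to z through the standard normal quantile
  (`scipy.stats.norm.ppf`); p = 50 returns M exactly.
- Ages between tabulated months interpolate L, M, S component-wise
  linearly (exact on the grid); the classifiers themselves only ever query
  exact month rows, so interpolation matters only for sparse references.
- |z| > 5 is logged as biologically implausible but not rejected — the
  screening protocol defines no plausibility filter, and rejection would
  silently change counts.

## Measurement reconciliation

Duplicate readings at 0.1 resolution: two readings agreeing within the
tolerance (0.1 kg for weight) record their mean; otherwise a third is
required and the mean of the closest pair is recorded; an equidistant tie
(readings in arithmetic progression) records the mean of all three.
Recording rounds half-up to 0.1. Arithmetic runs in `decimal.Decimal` so
0.1-resolution inputs behave as written (mean of 32.5 and 32.6 is exactly
32.55 → 32.6), which binary floats cannot guarantee. Recording the mean
of two agreeing readings (rather than either one) is the package's
choice: unbiased, and identical to either reading when they agree
exactly. The same rule applies to heights when multiple height readings
are supplied, though the pipeline defaults to single height readings.

## Agreement statistics

The 2×2 table takes the direct BMI arm as the reference classification
(columns) and the screening instrument as the comparator (rows). Overall,
positive and negative percent agreement are the primary readouts; a
statistic whose margin is empty (a+c = 0 or b+d = 0) is reported as
undefined, not as 0 or 100. Cohen's kappa is available as a clearly
optional chance-corrected extra. Presentation mirrors how such tables are
printed: integer agreement percentages, cell percentages truncated (not
rounded) at 2 dp; machine-readable outputs always carry full precision.

## Synthetic data

`synthref.py` provides synthetic month-by-month LMS curves — piecewise
linear in age through realistic anchors (heights ~110→176 cm, median BMI
~15→22 kg/m² with right skew, L < 0, S ~0.09–0.14) — labelled synthetic
throughout; they are not the published WHO 2007 tables, and any check
that depends on the real WHO numbers requires those tables to be supplied
by the user as delimited text.

`cohort.py` draws cohorts with the validation study's structure: n = 168,
ages uniform on 72–143 completed months (the study reports only mean ±
SD, 107.6 ± 18.2, which uniform-on-the-eligibility-window approximates),
sex Bernoulli with 47.6% girls, and (height-z, BMI-z) bivariate normal
pushed through the references; weight is derived as BMI × (height/100)²,
which pins the BMI-z marginal exactly and keeps weight–height coherence
within each child. BMI-z ~ N(0.4, 1.0²) matches the study's descriptives;
the height-z marginal N(0.3, 1.0²) and the z-correlation 0.3 are package
defaults chosen once so the synthetic height and weight marginals land
near the study's (the study reports no joint structure — these are
modelling choices, not estimates). Heights and weights are recorded to
0.1 by default, mirroring the measurement protocol. The degenerate-sd
spec collapses to identical children per (sex, age), which pins the
generator's plumbing in tests.

What the generator does *not* emulate: the real cohort's age distribution
beyond its support, secular/ethnic height structure, measurement error
beyond 0.1 rounding, and any covariate structure (sociodemographics,
questionnaire responses). Pipeline tests on synthetic cohorts therefore
demonstrate the *structural* properties of the instrument (c = 0, 100%
positive agreement, threshold bookkeeping), and plausibility of the
descriptive summaries — not numerical equality with the study's Table of
descriptives, which would require the undeposited patient data.

Gender comparisons in `summarize_cohort` use Welch's unequal-variance
t-test — the robust default reading of an unspecified "independent
t-test".

## Pipeline

`run_comparison` classifies every child with both arms; children outside
reference or table coverage are excluded with a recorded reason
(classified + excluded = input — auditable, mirroring clinic intake).
Per-child thresholds, matched grid cells and clamp flags are persisted in
the classified output so any individual decision can be reconstructed.
Outputs are written atomically and are byte-identical across re-runs of
identical inputs and seed.

## Problem sizes

Tests run the property suites at desk scale: 1000-tuple round-trip
scans, 29 × 11 tables, 20 default cohorts of n = 168 for the structural
agreement property, and one n = 5000 cohort for moment recovery (3
standard errors on the mean and SD, 0.05 on the correlation). The
acceptance script uses one n = 168 run and one n = 5000 run, seeded from
its `--seed`.

## Known limitations

- The exact percentile set and height-rendering convention of the
  published instrument are not fully pinned by its description; the
  defaults here reproduce its printed example cells to within ±0.2 kg.
- Under-5 standards, CDC references, thinness (−2 SD) categories and LMS
  curve re-estimation are out of scope.
- Interpolation between reference months is linear; nothing in scope
  exercises a finer scheme.
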