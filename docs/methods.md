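# Methods

## The data model

The unit of analysis is a per-metabolite panel: a subjects × timepoints
matrix of strictly positive serum concentrations with a missingness mask,
built by pivoting a long-format table (`subject_id, sex, metabolite,
time_h, concentration`). The default study design is 34 subjects (18 male,
16 female) sampled at 14 timepoints — a pre-meal reference at 0 h and
post-meal draws at 15, 30, 45, 60 and 90 min and 2, 3, 4, 6, 8, 10, 12 and
24 h. Time is encoded in decimal hours; minute-labelled input columns are
converted explicitly on read.

Concentrations ≤ 0 are rejected with line-numbered messages rather than
offset or imputed: negative values are not possible for these assays, and
a zero indicates a data-handling problem the analyst should see.

## Geometric statistics

All location/spread summaries are computed on natural-log concentrations
and back-transformed: gMean = exp(mean ln y), gSD = exp(sd ln y) with the
n−1 denominator, gSE = gSD^(1/√n), and gCI = gMean ×/÷ gSE^z with z = 1.96
by default. Conventions that matter:

- **Natural log.** Any base is self-consistent, but the gSD^(1/√n) relation
  and the sample-size arithmetic below assume one fixed base throughout.
- **n−1 denominator.** Required for the solve-for-n below to land on 32.
- **z = 1.96, not a t-quantile.** With n = 34 a t-based interval would use
  2.03; z is kept as the convention (and as the exponent in the MoE
  definition). The consequence, confirmed by simulation, is slight
  undercoverage: about 94% empirical coverage at n = 34 instead of 95%.
  `z` is an explicit argument everywhere for users who want t-quantiles.
- Timepoints with fewer than two observations get flagged summaries (NaN
  gSE/gCI) rather than errors; n is reported per timepoint because
  participation can be partial.

## Relative change from individual baselines

Per-subject ratios r_it = y_it / y_i0 are combined multiplicatively: the
cohort change at t is 100·(gMean(r_·t) − 1) %. Averaging signed
percentages arithmetically would be biased for multiplicative data and
ill-behaved for decreases; the geometric combination is also the only one
for which a subject-level rescaling (unit changes, stable level
differences, the male/female intercept offset) cancels exactly — a
property the test suite asserts. Uncertainty is reported as the gCI of the
ratios mapped through the same transform and labelled as such
(`relchange_interval` in every output header); percent-change intervals
are a convention choice, and this one keeps the interval interpretable as
a ratio interval.

Peak and nadir are the argmax/argmin of the percent change over
post-reference timepoints, ties broken toward the earliest timepoint (a
documented convention; real panels essentially never tie).

Subjects missing the reference sample cannot be normalised and are
excluded from the ratio analysis (and reported); subjects missing some
post-baseline cells contribute wherever observed.

## ICC: two-way random effects, absolute agreement

On log concentrations the model is y_ij = μ + b_i + u_j + e_ij with
independent normal subject, timepoint and residual effects. With one
measurement per cell an interaction is not identifiable, so the
no-interaction two-way model is used. The ANOVA moment estimator forms
MSS, MST, MSE from the row/column decomposition and sets
σ̂²_subject = (MSS−MSE)/k, σ̂²_time = (MST−MSE)/n, σ̂²_residual = MSE,
truncating negative estimates at zero (the standard convention; it keeps
the ICC in [0, 1]). Before truncation the ratio equals the familiar
closed form (MSS−MSE)/(MSS + (k−1)MSE + (k/n)(MST−MSE)), an identity the
tests check on random panels, along with agreement with an independent
ICC(A,1) implementation.

Note the timepoint component counts against agreement: a metabolite with a
strong meal response has large u_j variance and therefore a low ICC even
if subjects are perfectly rank-stable. That is the intended reading — the
ICC here measures how well a single sample taken at an arbitrary time
represents a person's level.

**Missing data.** Listwise deletion: subjects with any missing timepoint
are dropped before the balanced ANOVA and the count is reported
(`n_dropped`, and `icc_missing_data=listwise` in output headers).
Unbalanced moment estimators exist, but with a single partially-observed
subject the difference is negligible and the balanced closed forms are
exact and transparent.

## AIPE sample-size design

The design criterion is precision, not power: require the 95% gCI
half-width factor — the multiplicative margin of error MoE = gSE^z — to
stay below a bound. Since MoE and gSE bounds are equivalent
(gSE_max = MoE_max^(1/z)), either may be given. Solving
gSD^(1/√n) = gSE_max gives n = (ln gSD / ln gSE_max)².

- **Rounding.** Default `nearest` ((ln 1.32 / ln 1.05)² ≈ 32.4 → 32);
  `up` gives the strict guarantee (33 for the same inputs).
- **Stating the bound.** The conventional planning recipe rounds
  MoE < 1.10 at z = 1.96 to gSE < 1.05 and solves with 1.05; solving
  against the exact 1.10^(1/1.96) = 1.0499 would give 33. The pipeline
  default therefore states the bound as gSE ≤ 1.05.
- **Dropout.** Recruitment target = ⌈n / (1 − dropout rate)⌉.
- If one observation already meets the bound the design returns n = 1
  with a warning flag instead of failing.

**Bootstrap MoE distribution.** To see what precision a chosen n buys
across a whole metabolite panel, each cell of a reference precision table
contributes `reps` simulated estimates: in raw mode a cell's measurements
are resampled with replacement (nonparametric bootstrap); in gSD-table
mode, when only per-cell gSDs are available, a parametric log-normal
sample with that cell's gSD is drawn. Each draw yields a realised
gSE = ĝSD^(1/√n) and MoE = gSE^z; the pooled distribution, its quantiles
and the fraction of estimates meeting the bound are returned. Cell-level
random streams are spawned from the seed independently of iteration
order. Both modes are provided because published resampling procedures
rarely specify the unit of resampling; the mode is recorded in the result.

Quantiles (for the MoE distribution and for summarising gSD tables) use
numpy's default linear interpolation between order statistics; the
convention is fixed and documented rather than configurable.

## The synthetic-data generator

The generator simulates exactly the model the ICC assumes — log-normal
concentrations with subject, timepoint and residual effects and no
interaction — so reliability and recovery tests have a known truth:
population ICC = σ²_subject / (σ²_subject + σ²_time + σ²_residual).
Trajectory means follow m(t) = ln(baseline) + amplitude·s(t) with a shape
library chosen for qualitative realism, all satisfying s(0) = 0:

- `early_peak`: s(t) = (t/t_peak)·exp(1 − t/t_peak), the
  absorption–elimination hump with unit maximum at t_peak (glucose,
  most amino acids);
- `late_rise`: zero until t_onset, then a linear ramp reaching 1 at the
  final timepoint (branched-chain amino acids during prolonged fasting);
- `dip_then_rise`: the late ramp minus 0.5 × the hump (homocysteine,
  cysteine);
- `decline`: a monotone non-positive ramp reaching −1 at the end;
- `flat`: identically 0 (the pure two-way random-effects model).

The closed forms are modelling conveniences; only their qualitative
behaviour (peak within ~3 h, rise from 6–8 h, early dip, decline) is
meant to be realistic. Sex enters as a log-scale intercept shift for
males only — levels differ, relative changes do not, and the tests verify
the shift cancels in the ratio analysis. An optional dropout switch
truncates one subject after their first eight blood collections (through
3 h on the default grid), emulating a participant who withdrew during the
visit but remains in available-case analyses.

The default profile library (`default_profiles()`) covers the five shape
families with amplitudes set to representative reported magnitudes
(glucose +41.8% at 15 min; leucine +37.2% at 24 h; homocysteine +11.4% at
24 h after an early dip; a large early proline peak; a
pyridoxal-5′-phosphate decline) and variance components giving ICCs in
the 0.2–0.8 band these biomarkers span.

The reference gSD table generator draws cells uniformly; its default
range (1.1067, 1.3733) is solved in closed form so the cell distribution
has median 1.24 and 80th percentile 1.32, the published spread of a large
public metabolic-challenge panel that motivates the 1.32 planning gSD.

**What the generator does not emulate:** serial correlation of residuals
within a subject (residuals are exchangeable, as the ICC model assumes),
inter-metabolite correlation, meal-composition or hormonal dynamics, and
assay-specific error structure. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
violations of it.

Random streams are split per metabolite from the user seed (via a stable
hash of the metabolite name), so adding a metabolite to a simulation
never perturbs the draws of existing ones; identical seeds give
byte-identical output files.

## Problem sizes

Simulation-based checks use the study-scale panel (34 × 14): ICC
parameter recovery averages 200 replicate panels per true value and
checks the mean against truth within 0.03; gCI coverage uses 5000
log-normal replicates at n = 34; the bootstrap precision simulation runs
the full 132 × 56 × 50 = 369,600 estimates. The complete test suite and
the acceptance script each run in well under a minute.

## Known limitations

- The moment-estimator ICC is slightly biased downward in finite samples
  (visible as ~0.81 mean recovery at truth 0.82); no bias correction or
  confidence interval is provided.
- Percent-change intervals are ratio-scale gCIs, one convention among
  several; headers label the choice.
- No power analysis, no multiplicity adjustment across metabolites, and
  no unbalanced-data ICC: these are outside the package's design scope.
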