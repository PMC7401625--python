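# Methods

This note records the statistical model behind `vetri`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical choices that matter for reproducibility.

## Transference validation

The decision rule operates on batches of 20 values drawn without
replacement from a random permutation of the cohort (one seeded
permutation per analyte; per-analyte seeds are derived from the master
seed and the analyte name via SHA-256, keeping them stable across
platforms and below 2³¹). Counting is strict: a value outside the claimed
interval means strictly below the low limit or strictly above the high
limit, so values exactly on a limit are inside.

One boundary of the rule is internally ambiguous in its common prose
statement ("rejected if more than 25% … 5 or more"): 5/20 is exactly 25%,
and published worked tables show second rounds run at 25%. `vetri`
therefore sends `c₁ = 5` to round 2 and reserves immediate rejection for
`c₁ ≥ 6`. With the second-round threshold at 2, the rule's operating
characteristic as a function of the true outside-probability `p` is

    P(validate) = P(B ≤ 2) + P(3 ≤ B ≤ 5) · P(B′ ≤ 2),  B, B′ ~ Bin(20, p)

which equals 0.9940 at `p = 0.05`. The test suite checks seeded
Monte-Carlo rates against this closed form at several `p`, and
`rule_operating_characteristics` reports both the simulated rate and the
exact value for any shift/scale scenario grid.

If a second round is triggered with fewer than 40 values available the
run raises an error rather than silently reusing round-1 subjects.

## Outlier screening

Quartiles are Tukey hinges (median of each half, halves including the
overall median at odd n); this convention is explicit because statistical
packages disagree and the fences move with the hinge choice. Inner fences
sit at hinge ± 1.5·IQR, far fences at ± 3·IQR; both factors are
arguments. Values beyond an inner fence but within the far fence
("suspect") are retained; only far values are removed, in one pass —
fences are not recomputed after removal. A value exactly on a fence takes
the milder label, and a zero IQR (heavily tied data) labels everything
inside, so tied datasets are never trimmed.

The Dixon–Reed criterion (extreme flagged when its gap to the nearest
neighbour exceeds one third of the range, strict inequality, no flags at
zero range) is computed and reported alongside but does not remove values
by default. How the two screens were to be combined when they disagree is
genuinely open; reporting-but-not-acting is the conservative default, and
`remove_dixon=True` opts in to removal.

## Gaussianity and transformation

The Anderson–Darling statistic is computed in the estimated-parameters
(composite) form with the Stephens small-sample correction
`A²·(1 + 0.75/n + 2.25/n²)` and the standard piecewise exponential
p-value approximation for that case; the implementation is checked in the
tests against an independent library implementation to ~1e-9 in p. The
significance level defaults to α = 0.05 (conventional; nothing in the
workflow is sensitive to mild changes). Transformation is attempted only
when the raw test fails: a Box–Cox fit by profile likelihood with λ
bounded to [−3, 3] (numerically stable and ample for clinical analytes),
with a positivity shift of `−min(x)` plus one display-decimal unit when
the sample contains non-positive values (eosinophil and basophil counts
can be 0.00). The verdict object records every intermediate statistic.
Histogram/Q-Q diagnostics are exported as numeric quantile pairs
(`qq_pairs`) rather than rendered graphics.

## Reference-interval estimators

Coverage is fixed at the conventional central 95% (configurable).

*Nonparametric*: ranks `r = p(n+1)` with linear interpolation between
adjacent order statistics, clamped to [1, n] — so n = 39 yields the
sample extremes and n = 119 the exact 3rd/117th order statistics. Two
numerical details: `p` is rounded to 12 significant decimals so that
`(1−0.95)/2` is exactly 0.025, and ranks within 1e-9 of an integer snap
to it, so exact ranks return pure order statistics rather than picking up
float noise.

*Parametric*: mean ± z₀.₉₇₅·SD on the working (raw or Box–Cox) scale,
back-transformed. The Box–Cox inverse clamps `λy + 1` at zero, returning
the support edge when a symmetric limit on the transformed scale falls
outside the image of the data scale.

*Robust*: iterated Tukey-biweight location (tuning constant 3.7,
fixed-point tolerance 1e-6, initialised at the median with MAD/0.6745
spread) and biweight-midvariance scale (tuning constant 9), limits at
location ± z·scale on the working scale. The constants are exposed as
parameters; the property the suite enforces is behavioural — agreement
with the parametric limits within 5% of the interval width on clean
Gaussian samples, and markedly smaller limit inflation than the
parametric route under point contamination. A zero MAD degenerates to
(value, value).

*Method selection*: n ≥ 120 nonparametric on raw data; 40 ≤ n < 120
robust (raw scale when the raw AD test passes, Box–Cox scale otherwise);
20 ≤ n < 40 robust with an explicit `UserWarning`; n < 20 refuses. The
thresholds follow the CLSI/ASVCP recommendation family for when
nonparametric ranks exist and when robust estimation is preferred.

*Bootstrap CIs*: percentile bootstrap, default 1000 replicates, 90%
level, seeded; resamples where the estimator fails (e.g. degenerate
draws) are dropped from the percentile computation. Bias-corrected
variants are out of scope. Limits are rounded to analyte display decimals
only at report time.

## Synthetic cohorts

The generator stands in for a blood-donor database that is not publicly
deposited. Each breed×analyte entry is a parametric family fitted to
printed summary statistics: `truncated_normal` (normal parent with the
printed mean/SD, truncated to the printed min/max) by default, and
`log_normal` (parent moment-matched to the printed mean/SD in closed
form, then truncated) for the right-skewed analytes — monocytes,
eosinophils, basophils, ALP — where the printed mean–median gaps indicate
skew. Sampling is inverse-CDF restricted to the truncation window, so
every generated value lies inside the printed range by construction.

Treating printed sample extremes as truncation bounds is a modelling
choice: it biases realised moments slightly (for the Ariégeois RBC entry
the asymmetric window shifts the mean by ≈ +1.1%). The bias is quantified
exactly by a quadrature/`truncnorm` oracle (`truncated_moments`) and
enters the tolerance budget of the moment-fidelity tests; an optional
calibration (`calibrate=True`, 2-d root-finding on the parent parameters)
removes it when exact post-truncation moments matter. Generated subjects
always satisfy donor eligibility (age uniform on [2, 8] years inclusive,
weight uniform on (25.5, 35.5] kg, balanced sexes).

What the cohorts deliberately do **not** emulate: cross-analyte
correlation (RBC–Hb–HCT and the derived indices MCH/MCHC are strongly
dependent in real blood; here every analyte is an independent marginal),
sex/age structure within a breed, analytic measurement error, and any
day-to-day or instrument drift. Passing tests therefore demonstrate that
the pipeline's decisions and estimators behave correctly for cohorts with
the published location/spread/range per analyte — not that real
multivariate donor data would reproduce any specific published limit.

## Replay of published decisions, and two documented discrepancies

Published validation tables print round-wise outside-percentages; since
every round holds 20 values, percentages divide by 5 back into counts and
the rule can be replayed without raw data. Replaying the packaged fixture
reproduces the published per-breed new-RI lists exactly for three breeds
(7, 9 and 7 rejected analytes) and the 12-analyte cross-breed union. For
two cells the publication contradicts its own rule — Bracco italiano MCHC
(60% outside, rule says reject, not listed) and Briquet Griffon Vandeen
Urea (35% outside, likewise) — and under the rule those breeds reject 11
and 6 analytes rather than the listed 10 and 5. The replay marks these
with an explicit `discrepancy` flag; fidelity to the stated rule and
reproduction of the printed artifact are kept separable, and the union of
12 is unaffected either way.

The published breed RIs themselves derive from the unavailable raw donor
data; they are packaged purely as a comparison fixture and are never
recomputed or matched digit-for-digit. The statistical acceptance checks
instead verify the estimators' operating characteristics (coverage
recovery at n = 5000, order-statistic oracle equality over n = 39..200,
robust/parametric agreement, and the 0.9940 validate rate) on seeded
synthetic data.

## Problem sizes

Monte-Carlo sizes used by the test and acceptance suites were chosen so
that assertions sit at ≥ 3 Monte-Carlo standard errors: 10⁴ runs for the
validate-rate check, 10⁵ samples for generator moment fidelity,
2–4·10⁵ fresh draws for coverage recovery, 1000+ replicates per
operating-characteristic scenario.
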