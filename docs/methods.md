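# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions a maintainer would want recorded.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Units and panel conventions

All steroid concentrations are ng/dL internally; LH/FSH are IU/L. The
published cohort table mixes units, and several of its labels are internally
inconsistent; the reconciliation adopted (each entry overridable through
`pathway_analysis.normalize_units` and the unit sidecar) is:

* testosterone, androstenedione, DHEA and the Δ5 steroids: ng/dL as printed;
* cortisol and cortisone: μg/dL × 1,000 (their calibration ranges are stated
  in μg/dL);
* progesterone: treated as ng/mL × 100 despite its ng/dL column label
  (follicular progesterone of ~0.1 ng/dL would be three orders of magnitude
  below any physiological value);
* the "ng/mL" labels on 17OH-progesterone and 17OH-pregnenolone: treated as
  ng/dL (their printed values are already in the physiological ng/dL range).

DHEAS is carried alongside the panel for group comparison but excluded from
all enzyme ratios (sulfated storage pool). Conversion factors: μg/dL ×1,000,
ng/mL ×100.

## Limit of quantification

`loq_substitute(value, loq) = max(value, loq)` — values below an analyte's
LOQ are replaced by the LOQ itself before summaries, tests or ratios. The
default LOQ table reads the floors visible in the published cohort table
(pregnenolone 35, deoxycorticosterone 16, 11-deoxycortisol 15,
17OH-progesterone 17, 18OH-corticosterone 7.8 ng/dL), uses the stated lower
calibration bounds where available (cortisol 50 ng/dL), and defaults the
remaining analytes to 25 ng/dL, the bottom of the common calibration range.
No per-analyte LOQ list was published; the table is user-overridable.

A consequence worth noting: for pregnenolone, deoxycorticosterone and
11-deoxycortisol the published *median* sits on the LOQ floor, so more than
half of the underlying values were censored and the latent median is
unidentified beyond "≤ LOQ". The generator sets the latent log-normal median
to 0.7 × LOQ — any value below the LOQ reproduces the printed floor after
substitution; 0.7 keeps a realistic censored fraction (~60–70%) without
pinning essentially all mass below the limit.

## Synthetic cohort generator

Between-subject concentrations are log-normal per analyte, parameterized by
the target median *m* and 97.5th percentile *q*: log X ~ N(log m, σ²) with
σ = (log q − log m)/1.96. Rationale: steroid concentrations are positive and
right-skewed; a two-parameter family cannot also match the 2.5th percentile,
which is therefore diagnostic only. Joint structure: a Gaussian copula on
the log scale places a single configurable correlation (default 0.3) on
every pathway-adjacent (precursor–product) analyte pair; no joint structure
was published, and the copula is repaired by eigenvalue clipping if an
adjacency pattern makes it indefinite. Age and BMI are drawn from the same
two-quantile log-normal scheme per group, reproducing the published medians
and the BMI matching between groups.

Default sizes are the study's: 52 PCOS, 42 controls, 32 daily-sampled
normative controls. The 18OH-corticosterone row is printed identically for
both groups in the source table — likely a transcription artifact — and the
generator deliberately treats the two groups as genuinely identical for
this analyte.

Each generator draws from a domain-keyed RNG stream
(`SeedSequence(seed, spawn_key)`), so passing the same integer seed to two
different generators never produces correlated draws.

## Cycle-series generator

One row per subject-day; day 1 is the first day of menses; integer cycle
lengths are uniform on 25–35 days, and each subject loses 0–4 random days
(the study's missed-sample allowance). The per-analyte mean is a baseline
plus up to two Gaussian bumps whose centers are *fractions* of the
subject's cycle length (midcycle ~0.48, midluteal ~0.75), so the surge
tracks each subject's own cycle; the published figures motivate but do not
specify a functional form. Defaults emulate the four hormones tracked
daily: an LH surge (8 → ~40 IU/L, width 1.2 d), a luteal
17OH-progesterone rise, and shallow midcycle modulation of testosterone
and androstenedione around their control medians. Residual noise is
mean-one multiplicative log-normal at CV 20% by default (0 gives the exact
mean function). No ovulation re-alignment is performed — the band fitting
uses raw cycle day, matching the published analysis.

## Paired-assay bias model

Comparator = reference × exp(N(log b, s²)). The percent difference of a
pair, d = 200(R − 1)/(R + 1) with R the ratio, has analytic moments under
this model computed by Gauss–Hermite quadrature
(`expected_percent_difference`); `calibrate_assay_bias` inverts them by
nested bracketing root-finds, so a target mean/SD (e.g. the published
testosterone 31 ± 38%) maps to a unique (b, s). Percent differences are
bounded in (−200, 200) by construction.

## QC and calibration generators

Replicates combine a per-run mean-one log-normal effect (between-run CV)
with within-run log-normal noise; both CVs of 0 are exact. The total CV of
the product is √((1+cv_b²)(1+cv_w²) − 1), within ~0.1 point of
√(cv_b²+cv_w²) at the assay's levels. Calibration series multiply nominal
levels by mean-one log-normal noise; the CV may be a scalar or per-level.
The default "study profile" log-interpolates the CV from 13.1% at the
bottom of the 25–10,000 ng/dL range to 4.6% at the top — the span of the
assay's published inter-run CVs. This level dependence matters: applying
the single worst CV to every level is unrealistically pessimistic for a
mass-spectrometry calibration (precision is worst near the quantification
limit) and would contradict the assay's own r > 0.99 linearity claim, which
the level-dependent profile reproduces in >95% of seeded series.

## Precision estimators

Intra-run CV is 100·SD/mean with the n−1 SD. The inter-run (total) CV uses
one-way variance components over runs: pooled within-run mean square plus
the moment estimate (MSB − MSW)/n₀ of the between-run variance, truncated
at zero, all divided by the grand mean. Whether a published "inter-assay
CV" means total or purely between-run CV is ambiguous; total CV is the
default and `between_only=True` gives the alternative.

## Method comparison

Regression is OLS of comparator on reference (Deming regression available
as an option; only "linear regression" was specified). Limits of agreement
use exactly ±2 SD, not ±1.96, following the source's own convention. The
group comparison of discrepancies uses Welch's unequal-variance t test (the
variant was unspecified; Welch is the safer default). An optional phase
filter restricts pairs to a cycle phase (e.g. follicular-only progesterone)
when a phase column is present.

## Reference bands

λ is estimated once per analyte on all control observations pooled across
days (stabilizes the estimate; nothing suggests a per-day transform), by
profile likelihood over the fixed grid λ ∈ {−2.0, −1.9, …, 2.0}; λ = 0 is
the log. A constant sample carries no shape information: λ is defined as 1
with a warning. The mean curve is a cubic smoothing spline fitted to the
per-day means with day counts as weights, smoothing chosen by generalized
cross-validation (no criterion was specified; GCV is the standard
data-driven choice). With fewer than five distinct days — below the
spline's minimum — an exact low-degree polynomial through the day means is
used instead. The residual SD is either constant (pooled residual SD) or a
degree-2 polynomial of the per-day SDs against day, selected by a nested F
test at α = 0.05; degree is capped at 2, per-day SDs are unweighted (a
weighted option exists), days with fewer than two observations borrow the
pooled SD, and polynomial predictions are floored at 5% of the pooled SD.

The band is the back-transform of mean ± 2 SD; under the transformed-normal
model the upper curve is the ≈97.7th percentile, interpreted as the "97.5%
limit" (the 2-vs-1.96 SD discrepancy follows the source's stated
convention). Back-transform is the exact inverse on the transform's domain;
out-of-domain points are clipped to the boundary. For λ < 0 the transform
is bounded above by −1/λ, so when mean + 2 SD reaches that asymptote
(typically at the LH surge) the back-transformed upper limit is effectively
unbounded; those grid days are flagged in `ReferenceBand.upper_saturated`
and should be read as "no finite upper limit". Samples at days outside the
fitted grid are classified against the nearest grid day.

## Pathway ratios

The enzyme → (precursors, products) map is a documented reconstruction (the
published ratio table does not state its analyte sets): parallel Δ5/Δ4
branches are summed and the percent is 100·Σproducts/Σprecursors. The map
is validated at load and editable as YAML. Consistency checks support this
reading: testosterone/androstenedione ×100 on the published PCOS medians
gives 24.2% against a printed per-subject median of 22 for 17β-HSD, and the
11β-hydroxylase row is of order 10⁴% exactly as expected once cortisol's
μg/dL scale is converted. The total androgens-and-precursors statistic sums
pregnenolone, 17OH-pregnenolone, DHEA, 17OH-progesterone, androstenedione
and testosterone per subject and reports the median of per-subject sums —
which is why the column sum of published medians (1,347 ng/dL) differs from
the published median sum (1,607 ng/dL); both statistics are computed, and
they coincide only for symmetric data. Progesterone is excluded from the
total (negligible mass, shared with the corticoid branch); DHEAS from all
ratios.

## Group statistics

Summaries use linear-interpolation empirical quantiles (no convention was
published). The rank-sum test is exact (scipy's exact null distribution)
when the combined sample is ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections; the test suite checks
the exact branch against an independent brute-force enumeration over all
labelings. The adjusted p is the Wald p for the analyte coefficient in a
maximum-likelihood logistic regression of group on (analyte, age, BMI) —
group-as-outcome is the stated design; the analyte-as-outcome OLS direction
is available as an option. Complete or quasi-separation is detected and
flagged as boundary-unreliable rather than silently reported. The cohort
table mirrors the published layout: the age row carries no adjusted p, the
BMI row adjusts for age only. No multiple-testing correction is applied by
default, mirroring the source (a Benjamini–Hochberg helper exists but is
off).

## Problem sizes

Monte-Carlo checks use the sizes at which their tolerances are meaningful:
n = 5,000 cohorts for quantile round-trips (3% tolerance), 10,000 pairs for
Bland–Altman moments (±2 points), 500 seeded series for the linearity rate,
10,000 points for band coverage (95.4 ± 1.5 points), 2,000 replicates for
type-I-error rates ([3.5%, 6.5%] at α = 0.05). These sizes make the whole
suite run in well under a minute on one CPU.

## What the generators do not emulate

Chromatographic peaks, ion counts and raw spectra (the pipeline starts from
quantified concentrations); assay carryover and matrix effects;
within-subject longitudinal correlation in the cross-sectional cohort;
ovulation-timing heterogeneity beyond cycle-length scaling; measurement
rounding. Passing tests therefore demonstrate that the *statistical
machinery* is correct and calibrated, not that real cohort data would
reproduce the published group differences.

## Known limitations

* The log-normal family matches two quantiles per analyte; published 2.5th
  percentiles are reproduced only approximately (they are checked as
  diagnostics, not fitted).
* Box-Cox with strongly negative λ yields saturated (effectively infinite)
  upper limits near surge days; the flag above makes this explicit, but a
  quantile-regression band would be a more robust alternative for LH.
* Ratio statistics are steady-state concentration proxies; they do not
  measure enzyme kinetics, and the default pathway map, while internally
  consistent with the published percentages, is a reconstruction.
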