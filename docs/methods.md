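# Methods

This note documents the models, numerical choices, and defaults behind
`whalemorph`, and what the synthetic-data tests do and do not
demonstrate about real field data.

## Photogrammetric conversion and body area index

Pixel measurements convert to meters through the ground sampling
distance GSD = altitude · (sensor width / focal length) / image width
(m px⁻¹). Altitude is meters above the animal; focal length and sensor
width are in millimeters; the conversion assumes nadir imagery, so no
lens-distortion or off-nadir correction is applied (out of scope).

Body widths are indexed at 5%, 10%, …, 95% of total length measured
from the rostrum tip (rostrum = 0). The dorsal surface area over the
20–90% head–tail range is the trapezoidal integral of the width profile
at the 0.05·TL station spacing; only stations inside the range are
required, and a missing interior station is an error rather than an
interpolation. The body area index is

BAI = 100 · SA / ((0.9 − 0.2) · TL)²,

i.e. surface area standardized by the squared length of the integrated
range. This normalization (following the BAI lineage in the UAS
body-condition literature) makes the index exactly invariant under
uniform rescaling of altitude or of all pixel lengths, which the tests
assert to 10⁻¹². Trapezoidal integration is the simplest rule
consistent with discrete width stations; for a smooth semi-elliptical
profile its error at 19 stations is below 2% and vanishes as stations
are refined (checked against fine-grid quadrature). A parabolic
(Simpson) rule would reduce quadrature error but couples adjacent
stations and buys little at 5% spacing.

Quality filtering drops, per measurement, any value scored 3 (poor) on
the 1/2/3 scale, removes known calves, and caps images per whale at
five, keeping records with the best (lowest) mean quality score, ties
broken by input order. The cap's selection rule is a package choice:
the field protocol says only "up to five high-quality images". When
several images of one whale survive, their per-image posteriors are
combined by averaging posterior means and pooling variances as (mean of
within-image variances) + (between-image variance of means) — the law
of total variance with images weighted equally. The combination rule is
configurable in the sense that callers can combine image posteriors
differently before the ANOVA stage; equal weighting is the default
because image-level precision differences are already inside the
posterior variances.

## Platform measurement-error model

Each UAS platform is calibrated from photogrammetric measurements of
known-sized objects (research vessel 18.62 m; floating boards 1.48 m,
1.27 m; vessel-mounted and floating objects 4.41 m, 2.00 m — matching
the platforms' published training objects). The observation model is

measured = true · (1 + b) + ε,  ε ~ Normal(0, σ²)

with a proportional bias b and additive scatter σ (meters) per
platform. This is deliberately simpler than the published hierarchical
altitude-error model: its job here is to produce honest per-whale
posterior means and variances for the downstream Monte Carlo ANOVA,
and the recovery and coverage tests define "honest". Stratifying
calibrations by altimeter source (barometer vs laser) amounts to
fitting separate platform IDs.

Priors are weakly informative: b ~ Normal(0, 0.1²) (biases beyond
±10% are implausible for calibrated cameras) and σ ~ Half-Normal with
scale 5% of the median known object length. The two-parameter posterior
is computed exactly on a 161×161 grid over (b, log σ): a Nelder–Mead
MAP search plus a Laplace curvature estimate set the grid to ±7
posterior SDs, the posterior mass on the grid boundary is reported as a
diagnostic (analogous to a chain-convergence check; it should be ≪
10⁻⁴), and ≥1000 joint draws are resampled from the grid with within-
cell jitter, all deterministically under a seed. A scatter floor at
e⁻¹⁰ × prior scale keeps the log-σ posterior proper when calibration
residuals are exactly zero (in that degenerate case the posterior
concentrates at the floor, i.e. "σ near its prior lower range").

Posterior prediction inverts the observation model over the joint
draws: true = (observed − ε*)/(1 + b) with fresh ε* ~ N(0, σ²) per
draw, summarized by sample mean and variance. TL-standardized measures
and BAI inherit uncertainty by transforming the *joint* length draws
(ratios and the width-profile integral per draw, with the bias draw
shared across all measurements of an image) rather than by first-order
propagation — so, e.g., a pure proportional bias cancels exactly in
RB/TL, which a delta-method treatment would only approximate.

An important coverage subtlety, reflected in the tests: all whales
measured through one calibration dataset share that dataset's
bias-estimate error, so per-whale predictive coverage is only nominal
over the joint generative process (calibration re-drawn across
replicates). The coverage checks therefore re-draw calibration data per
replicate.

## Monte Carlo ANOVA and HPDI

For each measurement, each replicate draws one value per whale from
Normal(posterior mean, posterior variance) and fits a one-way ANOVA of
population on the measurement. The ANOVA uses cell-means coding, so the
per-replicate coefficients are exactly the group means and "difference
between coefficients" is the group-mean contrast; treatment coding
would shift coefficients but leaves every contrast identical. With
cell-means coding the replicate fit has the closed form group-mean =
draws · indicator/n, which is what the implementation vectorizes; the
zero-variance limit therefore reproduces closed-form OLS to machine
precision, and that equivalence is asserted against an independent
least-squares solution on random designs.

Draws are deliberately *not* truncated at zero — the procedure is the
stated Normal parameterization — but negative draws are counted and a
warning is emitted when any occur (they only arise for near-zero means,
which whale lengths never have).

The HPDI of a replicate distribution is the shortest contiguous window
of the sorted sample containing ⌈prob·n⌉ points, earliest window on
ties (ties are resolved after rounding widths at 10⁻¹² to keep the
earliest-window rule stable under floating-point noise). A pairwise
difference is significant exactly when its 95% HPDI excludes 0; no
p-values and no multiple-testing correction are computed, matching the
procedure this package implements.

Defaults: 10⁶ replicates in `RunConfig` (the full configuration);
drivers and tests use 10⁴–10⁵, which agree with 10⁶ within Monte Carlo
error (≈ SE/√n_reps scaling, asserted in the consistency test) and keep
runs desk-scale.

## Allometry and outlier screen

Scaling is OLS of log(part) on log(TL) per population on posterior-mean
point estimates (raw metric values, not TL-standardized ones — a ratio
would mechanically distort the slope). Slope 1 is isometry; the
classification uses the 95% slope CI: isometry if it contains 1,
otherwise positive/negative allometry by the side of 1. Before each
fit, Dixon's Q (r10 variant, two-sided on both extremes, supported for
3 ≤ n ≤ 30) screens for a single outlier against the standard
two-tailed critical table (Rorabacher 1991) at α = 0.05.

## Ocean seasonality

Season years are calendar years in the Northern Hemisphere and
July-start years in the Southern (so an austral summer is not split);
relabeling hemispheres only re-bins dates, never changes values.
Feb 29 is dropped for a uniform 365-day grid. Missing days contribute
zero to the cumulative sum and are counted per curve (conservative and
transparent; climatological infill would be the alternative), and a
season year missing more than half its days is excluded with a warning.
Signed series (zonal wind stress) are accumulated as-is without
rectification, so cumulative curves need not be monotone; windows are
then computed on the net curve.

The climatological mean is the day-wise mean of the per-year cumulative
curves. The f-fraction accumulation window runs between the
(1−f)/2 and (1+f)/2 crossings of the final accumulation, located by
linear interpolation on the piecewise-linear curve through (0, 0),
(1, C₁), …, (365, C₃₆₅); constant forcing gives exactly 182.5 days
(91.25 → 273.75). Degenerate rule: when both crossings fall inside the
same one-day segment — all relevant forcing on a single day — daily
data cannot resolve a sub-day window, and a zero-length window at that
day is reported. Whole-day labels for reports round half-up; window
lengths are reported unrounded. Both 0.5/0.8 (the default pair) and any
other fraction such as 0.9 are supported.

The SST upwelling index is offshore − nearshore by default (positive
when nearshore is colder, i.e. active upwelling); the sign convention
is a flag. Box averages over gridded fields are unweighted means of
cells whose centers fall in the closed lat/lon box, skipping missing
cells per time step; at the sub-5° boxes used here the cos(latitude)
area weighting would change means negligibly. Gridded inputs are read
as CF-convention classic NetCDF-3 via xarray's scipy engine. The
monthly chlorophyll climatology is the per-calendar-month mean with
per-year traces retained for plotting, and the salinity–chlorophyll
relationship is a standard Pearson correlation on date-aligned pairs.

## Synthetic data: what it emulates and what it does not

`synth` generates (a) populations with TL ~ Normal(≈22 m, 1.5 m) and
parts tied to TL by a·TL^slope with lognormal scatter (CV 3%),
anatomical bounds enforced by rejection with a counter; (b) a
semi-elliptical dorsal width profile scaled so each whale's true BAI
hits its Normal(population mean, SD 1) draw; (c) UAS observation
through the bias+scatter error model with calibration objects of the
published known sizes; and (d) daily forcing base + amplitude ·
vonMises(day; peak, κ) + noise, where κ maps monotonically to
seasonality (κ = 0 is a flat year). The default population presets
(31/17/15 whales; NZ−ENP BAI gap ≈ 1.3; standardized skull gaps ≈
0.01) are shaped to the magnitudes of the field comparison so the
end-to-end simulations are realistic in scale — they are illustrative,
not reproductions of the field data.

What passing tests show: the estimators are unbiased, calibrated, and
internally consistent under the assumed error structure. What they do
not show: robustness to effects the generator omits — body arching and
measurement-protocol differences between analysts, altitude-dependent
error (barometer drift), non-Normal posterior shapes, within-season
body-condition trends, or spatial structure in the satellite fields.
Conclusions about real populations inherit those assumptions.

## Problem sizes and tolerances

Test-suite and driver runs use desk-scale sizes chosen to leave Monte
Carlo noise well below the asserted tolerances: 10⁴ inner ANOVA
replicates (10⁵–10⁶ available and consistent within MC error), 500
outer replicates for type-I calibration, 200 replicates for coverage
and slope-CI checks, 25 independent datasets for effect recovery (a
single n = 15/17 dataset has contrast SE ≈ 0.11, so the dataset-mean is
the honest way to verify unbiasedness at ±0.15), and a 10⁻⁵-day grid
for the analytic window inversions. The error-model grid is 161²
(81² inside replicate loops, where the coarser grid changes summaries
by far less than a posterior SD).
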