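# Methods

`pinedrought` implements, end to end, the quantitative analysis of a
drought-timing experiment on Scots pine saplings: four treatments (control,
early-season hot drought, late-season hot drought, and both) observed through
half-hourly environmental sensors, point dendrometers, stem heat-balance
sap-flow sensors, weekly needle-length measurements and a destructive
end-of-season harvest.  Because no raw data from such experiments are
deposited, the package ships a first-class synthetic-data generator whose
defaults encode the experiment's published anchor conditions; every analysis
stage is tested against the generator's stored truth components.

## The change-point model of needle elongation

Needle length L on day of year t follows a continuous piecewise-linear
("truncated") regression

    E[L(t)] = b1 * min(t, T)  +  b2 * max(0, t - T),        L(t) ~ N(E[L], sigma^2)

with elongation rates b1, b2 (mm day^-1) before and after the cessation
threshold T (DOY).  The printed form is zero-intercept in raw DOY; the fit
optionally accepts a known growth-onset day `onset`, replacing the first term
by `b1 * max(0, min(t, T) - onset)`.  The generator uses onset DOY 118
(bud burst at the end of April), so well-specified fits pass that onset; the
zero-intercept form remains the default for raw use.

Inference is random-walk Metropolis MCMC over (b1, b2, T, sigma) under broad
independent uniform priors (defaults: b1, b2 in [0, 5] mm/day; T spanning the
observed DOY range; sigma in (0, 20] mm), 50,000 iterations with 40,000
discarded as burn-in, 3 chains.  Implementation details that matter:

- **Likelihood via sufficient statistics.** The Gaussian likelihood depends
  on the data only through per-unique-DOY counts, sums and sums of squares,
  making one iteration O(#sampling days) rather than O(#observations).
- **Proposal adaptation.** Diagonal adaptive Metropolis during burn-in:
  every 200 iterations each chain's per-parameter proposal SD is pulled
  towards 1.2x the chain's recent marginal spread (the 2.4/sqrt(d) rule),
  with an acceptance-driven global scale targeting ~30% (kept within the
  20-45% working band).  All adaptation freezes at the end of burn-in, so the
  retained draws come from a fixed Metropolis kernel.
- **Burn-in rejuvenation.** The posterior has a spurious quasi-mode with the
  threshold pushed to the prior edge and sigma inflated; a chain that starts
  there cannot cross the likelihood valley by small steps.  At each
  adaptation checkpoint a chain lagging the best chain by more than 50
  log-posterior units restarts at a jittered copy of the best state.  This
  affects discarded burn-in draws only.
- **Starts** are drawn from the best-scoring quarter of a 256-point uniform
  cloud over the prior box: overdispersed, but inside the support.
- **Convergence** uses the classic Gelman-Rubin potential scale reduction
  factor (pooled-variance estimate over mean within-chain variance), not the
  rank-normalised split variant, because the plain PSRF is the stated
  decision rule (< 1.1 per parameter).  Fits violating it carry
  `converged=False` and refuse treatment comparisons.
- **Summaries** are medians and equal-tailed 2.5/97.5 percentiles of the
  pooled post-burn-in draws; treatment effects are declared significant when
  the two 95% credible intervals are disjoint.  The threshold is treated as
  continuous; sigma is estimated rather than fixed, and observations enter at
  needle level (a per-tree-mean option exists).

`grid_mle` provides an exhaustive grid-search maximum-likelihood oracle; the
acceptance suite checks that posterior modes agree with it to one grid cell
(1-day threshold resolution).

## Zero-growth partitioning of dendrometer records

The stem diameter signal mixes irreversible growth with reversible
water-related shrinkage.  Under the zero-growth assumption the running
maximum `d_max(t)` carries all growth: daily net growth is the day-over-day
increase of the end-of-day running maximum (zero when the diameter never
exceeds its previous maximum), and tree water deficit is
`TWD(t) = d_max(t) - d(t) >= 0`.  The identity `d = d_max - TWD` holds
exactly at every timestamp, the partition is idempotent, and windowed growth
is the running-max difference across the window.  TWD is also expressed in
basal-area units, `(pi/4) (d_max^2 - d^2)` mm^2, after reconstructing the
absolute diameter from the pre-installation caliper value plus sensor
displacement.  Choices where the procedure is underdetermined: days are
calendar days (local midnight boundary); the daily basal-area TWD is the
mean of half-hourly values (an integral option is provided); no gap-filling,
jump correction or outlier screening is performed — a diseased tree is
handled by a configuration-level exclusion list.

## Sap-flow baselining and cumulative transpiration

Heat-balance sensors hold a 4 K difference between heated and reference
probes; transpiration is proportional to the power corrected for a slowly
varying instrumental baseline.  Nights with mean VPD below 0.2 kPa are
assumed flow-free; each such night contributes one anchor at its minimum
signal (the minimum, not the mean, to be robust against residual nocturnal
flow), and the baseline interpolates linearly through the anchors, held
constant outside the first/last.  Corrected power converts to flux as
`P / (c_w * delta_T)` with c_w = 4186 J kg^-1 K^-1, in kg/h; negative
corrected values are clipped to zero and the clip fraction reported as a
quality metric.  Nights run 21:00-05:00 local time (configurable).
Cumulative transpiration is the trapezoidal time-integral (1 kg = 1 l);
gaps longer than a day are inventoried and skipped.

Baselining is exact for any affine drift between consecutive anchors (a
property test draws random affine drifts).  For the generator's default
random-walk drift the anchor-free stress windows (no calm nights under
hot-drought air) leave a residual error of up to ~10% of seasonal
transpiration — a real limitation of night-anchored baselining that the
package reports rather than hides; the 5%-accuracy end-to-end check applies
to drift spanned by anchors.

## Bootstrap contrasts and utility statistics

Treatment-versus-control differences use a two-group bootstrap: both groups
resampled with replacement at their own sizes, difference of resampled means
recorded, 1,000 iterations; "95% of differences exclude zero" is read as the
equal-tailed 95% percentile interval excluding zero.  A relative mode reports
100 (mean_t - mean_c) / mean_c.  The suite calibrates the rule's null
false-positive rate against an independently coded nested Monte-Carlo
oracle.  One-way ANOVA is computed from the between/within decomposition,
Tukey HSD uses studentized-range p-values with Tukey-Kramer standard errors
for unequal n, and the compact letter display follows the insert-and-absorb
algorithm (groups sharing a letter are not significantly different).  The
bud-mass ~ leaf-area relationship is a pooled single-slope least-squares fit
with an F-test of zero slope.  Leaf area per age class is biomass x SLA.

## What the generator emulates (and what it does not)

The generator is phenomenological, not mechanistic.  Its defaults encode the
experiment's conditions: season DOY 100-300 half-hourly; stress windows DOY
163-191 and 225-253 with stepwise ramps (+2 C day / +1.25 C night every
2 days) to maxima 36.5 C / 3.5 kPa and 38.2 C / 4.0 kPa; soil water content
drying exponentially from ~37% to ~22% during unwatered windows; cessation
thresholds 205 / 183 / 202 / 173 (control / early / late / early-late) with
b1 = 0.8 mm/day, b2 = 0, 2 mm measurement noise (a ~65-day season then gives
~5 cm needles and a ~2 cm early-vs-control deficit); tree-level random
effects on the cessation day (SD 2 days) and elongation rate (SD 0.12
mm/day), because individual trees cease growth on different days and grow at
different rates — without them the population fit's credible intervals
collapse to ~1.5 days, an order of magnitude narrower than published fits of
such data, and 3-day treatment separations would always appear significant; a Gaussian-bell stem
growth season scaled so stressed windows grow at 45% of the control rate; a
VPD- and soil-drought-driven water deficit damped to 60% in early-late trees
during the second window (the leaf-area legacy); leaf-area trajectories
whose early-treatment endpoint yields a 40-50% seasonal transpiration
reduction; and a biomass table whose means reproduce the published harvest,
with higher SLA for stressed current-year needles so the early leaf-area
reduction is ~35% while leaf biomass drops ~43%.

Weather variation enters as "humid days" (probability 0.25) — only their
nights are calm enough (mean VPD < 0.2 kPa) to anchor the baseline, and
there are deliberately none inside stress windows.  Per-tree size factors
are fixed evenly spaced multipliers rather than random draws, so
treatment-mean effects in truth equal their configured values; sensor noise
remains random.  All streams derive from one master seed with fixed offsets
(adding trees never reshuffles existing series).  Not emulated: sensor
failures and data gaps, hygroscopic bark artifacts, temperature-dependent
sensor calibration, mechanistic plant hydraulics or photosynthesis, and the
leaf-water-potential campaigns are descriptive output only.  Passing tests
therefore demonstrate correctness of the analysis chain under the assumed
signal structure, not robustness to every failure mode of real sensors.

## Problem sizes and numerical choices

Default analyses fit 400 observations per treatment (8 trees x 2 needles x
25 weekly campaigns) with the full 50,000-iteration protocol (~3 s per fit);
the end-to-end pipeline test uses 20,000-iteration chains and the pipeline
wiring test 8,000, both comfortably within the convergence envelope measured
for this model.  Bootstrap inference uses 1,000 iterations.  Replicate-based
recovery checks use 20 seeded replicates per treatment.  Ties and degenerate
inputs: empty observation sets and single-day designs are rejected
(identifiability); zero within-group variance with equal means is a
degenerate ANOVA input; a constant regressor fails the slope test; windows
outside a record raise range errors rather than clamping.
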