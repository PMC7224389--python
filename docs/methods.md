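# Methods

This package implements the four analyses that a fossil human trackway
assemblage supports — travel-speed estimation, orientation statistics,
stature prediction, and group-composition inference — together with
synthetic generators for the two comparative datasets those analyses
are trained on. This note records the models, their assumptions, the
defaults and why, and what the synthetic data can and cannot show.

## Data model and units

A trackway is an ordered sequence of footprints attributed to one
individual. Lengths are millimetres (heel-to-hallux footprint length,
forefoot/heel breadths, stride lengths), velocities m/s, and compass
orientations degrees clockwise from north in [0, 360). Medians with an
even count are the mean of the two central values. The *relative
stride length* (RSL) — stride length divided by footprint length — is
the dimensionless gait indicator throughout: walking humans cluster
near 5–6, runners well above. For fossil trackways RSL uses the median
stride over the median footprint length; for experimental trials, the
trial stride over the trial footprint length.

The bundled assemblage stores the published per-trackway values (RSL,
gait, velocity, bearings, attributions, statures). The one published
per-trackway median footprint length is the largest trackway's
(289.5 mm, trackway D); the other medians are a synthetic
reconstruction scaled from D's in proportion to published stature.
They preserve the published size ranking exactly and are labelled as
reconstructions wherever they appear; nothing asserts them against
measured values.

## Speed estimation

Two-step procedure fit on experimental trials (41 subjects, 3 trials
at each of four self-selected speeds):

1. **Gait**: logistic regression of walk/run on RSL. The decision
   threshold maximizes Youden's J (TPR − FPR) on the training ROC; a
   probability exactly at the threshold classifies as run (documented
   tie-break). Weak L2 regularization (C = 10⁴) keeps the fit finite
   when gaits are linearly separable, where the ROC threshold — not the
   coefficient magnitude — carries the decision.
2. **Velocity**: per gait, a linear mixed model `velocity ~ RSL` with a
   random intercept per subject (REML). Fossil predictions use fixed
   effects only, with a ± population-level RMSE band and an
   extrapolation flag outside the training RSL range.

The linear-in-RSL form with subject random intercepts is a design
choice; the printed fossil velocities cannot distinguish it from, e.g.,
log-transformed variants, and we do not claim otherwise. Regressing
velocity on *footprint*-derived RSL (the only quantity available for
fossils) steepens the fitted slope by roughly 3% relative to the
anatomical-RSL relation, because footprint elongation grows with
speed; this is intrinsic to the fossil application, so
parameter-recovery tests that probe only the fitting machinery switch
elongation off in the generator.

## Orientation statistics

Vector-sum circular mean and mean resultant length R̄; a resultant
below 10⁻¹² reports the mean as undefined. Rayleigh's test of
uniformity uses Z = nR̄² with the standard small-sample exponential
approximation `p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))`, R = nR̄
(cross-checked against pingouin). Von Mises κ comes from the standard
three-regime inverse-A approximation, capped at 10⁶ for degenerate
all-identical samples (cross-checked against the scipy MLE).

Bootstrap CI of the mean direction: B resamples with replacement
(default B = 10,000; seed mandatory in the pipeline), von Mises ML
mean direction per resample, percentile interval computed on angular
deviations from the full-sample mean and re-centred on it — working in
deviations handles wrap-around at 0/360 and guarantees the interval
brackets the sample mean. This reproduces the published worked-example
intervals to under 0.1°. Known limitation: like any percentile
bootstrap of a mean, the interval undercovers by O(1/n); at n = 15 and
κ = 20 true coverage is ≈ 91.5–92.5% rather than 95%, approaching
nominal by n ≈ 60. Compass bearings are used as-is (no declination
correction).

Two-mode partitioning assigns each trackway to the nearer of two
circular means, initialized from the half-circles split at 135°/315°,
iterated to stability. Trackways without numeric bearings are excluded
from the statistics but retained in behavioral group counts via their
coarse direction labels.

## Stature estimation

Per-subject median footprint dimensions (length L, forefoot breadth
FB, heel breadth HB) from walking trials only; candidate OLS models
over the fixed predictor family {L}, {L,FB}, {L,HB}, {L,FB,HB}, {FB},
{HB}, ranked by 10-fold cross-validated RMSE (seeded shuffle). The
top-ranked model is applied to fossil trackway medians with an
extrapolation flag. Models are sex-pooled: the fossil application
cannot condition on sex. CV ranking stands in for a model selection we
cannot observe; the published fossil statures are not reproducible
without the original training subjects, so tests assert structural
properties (coefficient recovery on synthetic truth, monotonicity,
rank concordance) rather than printed values.

## Group-structure resampling

The core procedure infers the age/sex mix (adult male AM, adult female
AF, juvenile male JM, juvenile female JF) of the track-making group by
matching trackway size against a comparative sample of (sex, age, foot
length) records:

- **Adult/juvenile cutoffs**: foot-growth cessation at 14 yr (F) and
  17.8 yr (M) by default; ages at the cutoff count as adult. A
  reproducible surrogate for visual identification fits a continuous
  two-segment piecewise-linear model of foot length on age per sex
  (grid-profiled least squares) and flags breakpoints that land at the
  data boundary or improve on a straight line by < 1% of SSE
  (unidentifiable plateau).
- **Largest-track cutoff**: the largest trackway is assumed to belong
  to someone at least 1 SD above the comparative adult-male mean foot
  length; mean and sample SD (n−1) are computed once on the full
  comparative sample, before any downsampling.
- **Per iteration** (default 10,000, seeded): (1) cap every
  sex × 2-year age bin (half-open, anchored at age 0) at 50 records,
  sampled without replacement — redone every iteration, flattening the
  survey's 18–34 bias; (2) draw the largest trackway's foot uniformly
  among feet ≥ the cutoff; (3) every other trackway draws uniformly
  among feet inside (0.95 p, 1.05 p) × the drawn largest foot, where p
  is its median-to-largest-median proportion; (4) record each drawn
  person's category; (5) compute the four proportions, the adult sex
  ratio (nAM/nAF), the adult:juvenile ratio, and log dimorphism
  log(mean AM foot / mean AF foot).
- An iteration in which any window is empty is redrawn wholesale
  (fresh downsample and largest foot), up to a bounded retry count —
  this preserves a complete classification per iteration, the quantity
  the summaries aggregate. Ratios with zero denominators are stored as
  undefined and excluded from their percentiles with a reported count.
- **Summaries**: medians and 2.5/97.5 percentile intervals per
  quantity; per-trackway attribution probabilities over iterations,
  most-probable category with ties broken in fixed AM, AF, JM, JF
  order and flagged.

On small populations the Monte-Carlo attribution probabilities are
verified against exact enumeration (averaging eligible-set category
shares over eligible largest feet) within 3 MC standard errors.

## Synthetic data: what it emulates, what it does not

**Experimental trials.** Per trial, RSL is drawn per speed category
(normal walk 5.2 ± 0.35, fast walk 6.9 ± 0.45, endurance run
8.7 ± 0.45, fast run 10.4 ± 0.6) and velocity follows
v = α_gait + β_gait·RSL + subject effect + residual (walk: −1.104 +
0.452·RSL; run: −3.418 + 0.735·RSL; subject sd 0.05, residual sd
0.1 m/s) — coefficients chosen so category mean velocities land at
realistic 1.25/2.0/3.0/4.2 m/s. Stride = RSL × the subject's foot
(foot 245 ± 15 mm; stature = foot/150 m + 0.03 m noise). Footprints
are the foot times 1 + elongation, elongation ~
N(−0.011 + 0.012·v, 0.025): mean +2% overall, ≈ 23.5% of running
prints more than 5% long, well under 5% of prints more than 5% short —
the three published anchors of footprint-vs-foot variation. A
configurable number of trials (default 28, leaving 464 of 492) is
flagged excluded to mirror experimental attrition.

**Comparative population.** 1652 males and 1581 females aged 2–52;
integer-age sampling weights of 1 (2–17, 35–52), 3 (21–34) and 6
(18–20) reproduce the published bias toward young adults. Foot length
grows linearly from age 2 (130 mm F / 135 mm M) to the sex-specific
plateau (14 / 17.8 yr), then stays at the adult mean (228 / 252 mm),
with additive 10 mm noise — the simplest form consistent with growth
cessation. Adult means and noise follow typical anthropometric
surveys; population log dimorphism ≈ 0.10.

**Fossil assemblage.** Trackways generated from a known composition
(default 2 AM, 14 AF, 1 JM — the inferred structure of the
southwest-walking group), feet from per-category normals (AM 265 ± 10,
AF 228 ± 10, JM 200 ± 15, JF 195 ± 15 mm) or resampled from a supplied
population; per-print multiplicative noise from Beta(2,3) rescaled to
±5% (mean −1%: the published downward skew of print lengths about the
trackway median); strides via the inverse experimental velocity
relation at walking speeds (1.35 ± 0.1 m/s); bearings from two von
Mises modes at 45°/225° (κ = 100).

These generators match published *structure* — counts, category
layout, noise envelopes, growth form — but their parameter values are
nominal, not estimates of the unavailable source data. Passing
recovery tests therefore demonstrates that the estimators invert the
assumed generating processes at realistic noise levels, not that the
published point values are reproduced; the published per-trackway
velocities, statures, and composition medians depend on the original
comparative data and are out of reach by design. Conversely, all
orientation results are computed from published bearings and are
reproduced exactly.

## Numerical and reproducibility choices

Every stochastic stage takes an explicit seed; pipeline stage seeds
derive deterministically from one run seed, and identical configs
reproduce every output file byte-for-byte. Resampling ties
(equal-median trackways) break lexicographically by id. Problem sizes
in the test suite are scaled to keep the full suite under a minute:
recovery replicates use 2,000 resampling iterations (the estimand is a
median over iterations, insensitive beyond that), coverage simulations
use B = 1,000–2,000 bootstrap resamples, and CI-recovery checks use
200 seeded replicates. Headline analyses and the reproduction script
use the full B = 10,000 / 10,000 iterations.
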