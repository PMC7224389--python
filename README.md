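# trackways

Inference from fossil human footprint trackways: travel speeds,
directions of travel, statures, and the age/sex composition of the
track-making group.

A trackway — an ordered sequence of footprints left by one individual —
preserves behavior on a time scale no skeletal fossil can: minutes.
An assemblage of contemporaneous trackways on one surface therefore
supports questions about *groups*: who walked together, how fast, in
which direction, and what mix of adult males, adult females and
juveniles they were. This package implements that analysis chain for
assemblages like the Late Pleistocene human footprint surface at
Engare Sero, Tanzania (bundled as a fixture), for ichnologists and
biological anthropologists who want each step reusable, seeded and
testable.

## What it computes

- **Speed** (`trackways.speed`): relative stride length
  RSL = stride length / footprint length is the dimensionless gait
  indicator. A logistic classifier P(run | RSL) with a Youden-J ROC
  threshold separates gaits; gait-specific linear mixed models
  v = α + β·RSL + b_subject + ε (random subject intercepts, fit on
  experimental trials of habitually barefoot subjects) predict
  velocity with a ±RMSE band.
- **Orientation** (`trackways.orientation`): circular mean and
  resultant length R̄, Rayleigh's uniformity test Z = nR̄², von Mises
  (μ, κ) fits, and seeded percentile-bootstrap 95% CIs of the mean
  travel direction; two-mode circular partitioning splits opposed
  travel directions.
- **Stature** (`trackways.stature`): OLS regressions of stature on
  per-subject median footprint dimensions, ranked by 10-fold CV RMSE,
  applied to trackway medians.
- **Group structure** (`trackways.group_structure`): an iterative
  size-window resampling of a comparative anthropometric sample
  (sex, age, foot length). Per iteration, age bins are capped at 50
  records, the largest trackway draws a foot ≥ 1 SD above the
  adult-male mean, every other trackway draws uniformly among feet
  within (95%, 105%) of its size proportion times that foot, and each
  draw is classified adult/juvenile × male/female by sex-specific
  foot-growth cessation ages (14 yr F, 17.8 yr M). 10,000 iterations
  yield attribution probabilities per trackway and percentile CIs for
  the group's composition, adult sex ratio, adult:juvenile ratio and
  log foot-length dimorphism.
- **Synthetic data** (`trackways.synthetic`): seeded generators with
  known ground truth for the experimental trials, the comparative
  population and fossil assemblages — the original comparative
  datasets are not publicly archived, so every estimator is validated
  by parameter recovery against these generators.

`trackways.pipeline.run_full_analysis` orchestrates all four stages
and writes CSV reports plus a manifest that makes a run byte-for-byte
reproducible; the `trackways` CLI exposes `simulate`, `fit`, `analyze`
and `report`. The numbered scripts under `analysis/` run each stage as
a narrative step, writing tables under `results/`.

## Worked example

Directional statistics for the bundled assemblage (`python
analysis/03_analyze_orientations.py`):

```
6 trackways oriented northeast, 16 southwest with bearings, 3 without bearings (EE, FF, TT)
NE: mean 46.17 deg, R-bar 0.999, Rayleigh p = 3.46e-04, 95% CI (44.00, 48.33) deg
SW: mean 226.09 deg, R-bar 0.997, Rayleigh p = 2.16e-11, 95% CI (223.91, 228.25) deg
```

Both directional groups are significantly oriented (Rayleigh p <
0.05) and travel in almost exactly opposite directions; the tight CIs
(a few degrees wide) quantify how coherently each group moved. Speed
estimation (`python analysis/02_estimate_speeds.py`) then shows the
southwest group walking at similar paces while one northeast-directed
individual ran:

```
gait classifier: AUC 0.999, RSL threshold 7.57
walk model: v = -1.092 + 0.454 RSL (RMSE 0.141 m/s)
23 trackways: 1 running, 20 walking below 1.9 m/s
```

and the group-structure resampler (`python
analysis/05_estimate_group_structure.py`, 10,000 iterations against a
synthetic comparative population) attributes most trackways to adult
females:

```
           adult male proportion   0.240   0.120    0.440
         adult female proportion   0.600   0.440    0.760
        juvenile male proportion   0.080   0.000    0.240
      juvenile female proportion   0.040   0.000    0.160
most-probable attributions over 25 trackways: {'AF': 19, 'AM': 5, 'JM': 1}
```

Columns are the median and the 2.5/97.5 percentile limits over
iterations. Because the comparative population here is synthetic,
these composition numbers characterize the method, not the original
survey; the orientation results above are computed entirely from
published bearings.

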