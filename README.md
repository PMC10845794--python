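# swmap

Spatial weight-map analysis of orientation ensemble perception.

When observers report the average orientation of a briefly shown set of
Gabor patches, do they pool all elements equally, or do some locations —
above all the fovea — pull the estimate harder?  `swmap` implements the
regression pipeline that answers this from method-of-adjustment data, for
vision scientists running (or simulating) ensemble-averaging experiments
with 5×5 Gabor grids.

## The model

Orientations live on a 180°-periodic circle, so responses and stimuli are
first re-expressed relative to each trial's ensemble mean: the response
becomes a signed **error** ε and each element's orientation a **deviation**
δ (acute angle differences in [−90°, 90°)).  The *spatial weighted-average
model* (SWM) is then the per-observer linear regression

  ε_j = Σₖ wₖ δ_jk  (k = 1 … 25 locations),

solved by minimum-norm least squares (Moore–Penrose pseudo-inverse).  The
coefficients wₖ are integration weights: a uniform averager has equal
weights (all zero after sample-mean centring), an observer who over-weights
the fovea shows an inflated weight at the central location.  Weights are
standardised into regression t-scores (wₖ / SE(wₖ)) before group analysis,
tested against uniform pooling by location-shuffling permutations with
Bonferroni correction, and summarised as **bias scores** (t at a target
location minus the mean t elsewhere).

On top of the core fit the package provides:

- a synthetic-data module — 5×5 ensemble stimuli for four study designs and
  candidate observers (uniform, fixed-weight, reliability-weighted
  fovea/parafovea cue combination) with oblique-effect and duration-scaled
  encoding noise, so every analysis stage can be validated against ground
  truth;
- outlier handling (45° error cut, per-subject 1.5·IQR fence, 10 s RT cut,
  30° error-SD subject exclusion);
- the response–stimulus distance control metric and bilinear heat maps;
- condition effects: per-location weight slopes over ensemble σ or exposure
  duration, with permutation inference; repeated-measures ANOVA (via
  pingouin) and Cohen's d helpers;
- oblique-effect analyses: sliding-window central-bias curves over the
  folded 0–90° orientation axis and close/mid/far binning by the central
  element's distance to the oblique;
- serial-position analyses for jittered-onset designs: the location ×
  serial-position weight matrix, split-half cross-validated polynomial
  model comparison of bias timecourses, and cross-condition single-trial
  error prediction.

## Worked example

Simulate a variability-manipulation study (σ ∈ {5°, 10°, 15°}) with
reliability-weighted observers, then ask whether the central weight grows
with ensemble uncertainty:

```python
import numpy as np
import swmap

rng = np.random.default_rng(7)
design = swmap.exp2_design(n_trials_per_subject=300)
observers = [swmap.reliability_weighted_observer(name=f"S{i:02d}")
             for i in range(12)]
trials = swmap.simulate_dataset(design, observers, rng)

pre, log = swmap.preprocess(trials)
print(f"kept {int(pre['kept'].sum())}/{len(pre)} trials "
      f"({log.fraction_removed:.1%} removed)")

maps = swmap.fit_subject_maps(pre, condition_col="sigma_deg")
for sigma in (5.0, 10.0, 15.0):
    t = np.mean([res.tvalues[swmap.CENTER_LOCATION - 1]
                 for (subj, lvl), res in maps.items() if lvl == sigma])
    print(f"sigma {sigma:4.0f}: mean central t-score = {t:.2f}")

effect = swmap.condition_effect_map(maps, (5.0, 10.0, 15.0),
                                    n_permutations=10_000,
                                    rng=np.random.default_rng(8))
flagged = [int(k) for k in np.flatnonzero(effect.significant) + 1]
print(f"locations with a significant weight increase over sigma: {flagged}")
```

Output:

```
kept 3536/3600 trials (1.8% removed)
sigma    5: mean central t-score = 0.25
sigma   10: mean central t-score = 1.98
sigma   15: mean central t-score = 4.33
locations with a significant weight increase over sigma: [13]
```

The central t-score rises monotonically with σ — the reliability-weighting
signature: as the parafoveal average becomes noisier, the (unchanged)
foveal element earns more weight — and the permutation test singles out
location 13, the grid center, as the only location whose weight tracks σ.

A command-line interface mirrors the library (`swmap simulate`,
`preprocess`, `fit`, `group-test`, `oblique`, `conditions`, `temporal`,
`predict-cross`, and `swmap run -c config.yaml` for a whole seeded
pipeline; see `swmap --help`).

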