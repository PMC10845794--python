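# Methods

This note documents the models implemented in `swmap`, the assumptions and
parameter choices behind them, and what the simulation-based tests do and do
not establish.

## Circular preliminaries

Gabor orientation is 180°-periodic, so all angular statistics run on the
doubled angle 2θ.  The circular mean of a set of orientations is half the
argument of Σ exp(i·2θ), reduced into [0, 180); it is undefined (an error)
when the resultant length falls below 1e−9, e.g. for the balanced pair
{0°, 90°}.  Signed differences are acute angle differences,
((a − b + 90) mod 180) − 90, in [−90, 90) with exact perpendicularity mapped
to −90 (the half-open boundary).  The folded axis used by the oblique
analyses maps θ ↦ min(θ, 180 − θ), collapsing both cardinals onto the ends
of [0, 90] and both obliques onto 45.

## The spatial weighted-average model

Per observer (and condition), response errors are regressed on the 25
element deviations with no intercept: ε_j = Σ_k w_k δ_jk.  Both sides are
signed degrees relative to the trial's ensemble mean; the default reference
is the *sample* circular mean of the 25 presented orientations (so a
uniform averager has zero expected weights), with the generating mean of
the stimulus distribution available as a switch.

**Identifiability.**  With the sample-mean reference the deviations of each
trial sum to zero in the doubled-angle sense, and almost to zero
arithmetically; the weights are then identified only up to an additive
constant.  Numerically the design matrix is *near* rank-deficient — its row
sums are small but nonzero because circular means are not arithmetic means
— and a raw pseudo-inverse solve would retain the tiny-singular-value
common-offset direction, which absorbs noise with enormous variance
amplification (all 25 weights shift together by an arbitrary constant per
fit).  The fit therefore detects a centred design (root-mean-square row sum
below 0.2 of the design scale) and solves in the zero-row-sum subspace:
each row of X is mean-centred before the pseudo-inverse, which leaves the
fitted values untouched for any zero-sum weight vector and returns exactly
the zero-sum representative.  Uncentred (full-rank) designs are solved as
given.  All location-difference quantities downstream (t-score contrasts,
bias scores) are invariant to the additive constant, so this choice affects
stability, not substance.

**Standard errors and t-scores.**  Residual variance uses df = J − rank(X)
(rank, not 25, so the rank deficiency induced by centring does not zero the
df), and the coefficient covariance is σ̂²·pinv(XᵀX).  t-scores are
w_k / SE_k, with 0 where both are zero (the all-zero-error case).  t-scores
standardise weight maps across observers with different precision and trial
counts and are the group-analysis currency.

**Response–stimulus distance.**  As a model-free control, the mean absolute
acute distance between the report and each element's orientation; locations
that pull the report show small distances, mirroring the weight map.

## Group inference

Significance against uniform pooling uses location-shuffling permutations:
in each of 10,000 permutations every observer's 25 scores are independently
re-assigned to locations, group means recomputed, and the one-sided p-value
at each location is the add-one-corrected proportion of surrogate means at
least as large as the observed one (floor 1/(n_perm + 1)).  The alpha
criterion of 0.05 is Bonferroni-corrected over the 25 locations.  Fewer
than 100 permutations triggers a degraded-resolution warning.

Condition effects (ensemble σ, exposure duration) use a two-stage scheme:
SWMs per subject × condition, then a per-subject, per-location OLS slope of
the *raw weight* on the condition level; the slope maps enter the same
permutation machinery.  Slopes are computed on weights rather than t-scores
because t-scores confound weight changes with residual-noise changes — a
duration manipulation that rescales all encoding noise leaves weights, but
not t-scores, invariant.

Bias toward a location is its t-score minus the mean t-score at control
locations (default: all other 24); positive = bias toward the target.  The
sign convention is fixed so that the central bias is positive, matching the
direction shown in weight maps.  Repeated-measures ANOVAs are delegated to
pingouin, reported as F, dfs, p and partial eta squared via the identity
η_p² = F·df1/(F·df1 + df2); constant tables return F = 0.  Cohen's d is
mean/SD (n−1) of the tested values, an error when the SD is zero.

## Outlier handling

Trials are removed in a fixed order: (1) |error| > 45°; (2) a two-sided
per-subject fence at quartile ± 1.5·IQR on the remaining errors (per
subject because errors are subject-scaled; the rule is run once — fences
recomputed on their own output would keep shrinking); (3) RT > 10 s.
Subjects whose *raw* error SD (before trial removal) exceeds 30° are
excluded entirely: after the 45° cut the SD of kept errors is bounded near
26–31°, so only the raw distribution lets the rule identify guessing
observers (a uniform guesser has raw SD ≈ 52°).

## The synthetic-data generator

The generator emulates four study designs on a 5×5 grid (8° or 12° of
visual angle per side, ±0.25° position jitter — metadata only, the analysis
is position-blind): trial means uniform on a 10° grid (design 1) or 1° grid
(others); element orientations wrapped-normal around the mean with
σ ∈ {5, 10, 15}; exposure 500 ms, or {100, 500, 1000} ms in the duration
design; or element onsets drawn uniformly in [0, 500] ms of an 800 ms
window with 300 ms element duration (jittered design; an optional frame
grid quantises onsets and produces ties).  The default 400 trials per
subject corresponds to roughly an hour-long adjustment session; condition
cells are balanced exactly and trial order randomised.  RTs are lognormal
(median 1.5 s).

Observers:

- **uniform** — circular mean of all 25 elements plus motor noise
  (default 5°): the uniform-pooling null, used for calibration.
- **fixed_weights** — weighted circular mean with a fixed nonnegative
  profile; optionally the profile is a function of the elements' serial
  ranks (used to build linearly growing or U-shaped bias timecourses whose
  generative form matches the polynomial family being tested).
- **reliability_weighted** — a foveal cue (central element + encoding noise,
  default SD 12°) and a parafoveal cue (circular mean of the other 24 +
  noise 0.6·σ) combined by inverse-variance weighting along the shorter arc
  of the doubled-angle circle.  Only this observer predicts a central bias
  that scales with uncertainty.

Two further noise structures matter:

- **Oblique effect.**  Extra encoding noise amplitude·exp(−(d/15°)²), where
  d is the distance of the encoded orientation to the nearest oblique — a
  Gaussian tuning bump reflecting the narrow bandwidth of the oblique
  effect (a broad |sin 2θ| profile would barely differentiate close/mid/far
  bins, because with σ = 10° the central element rarely strays far from an
  oblique ensemble mean).  Foveal and parafoveal amplitudes are separate
  (defaults 0; the oblique simulations use 8° and 12°): pooling noisy
  parafoveal signals amplifies orientation-dependent noise, and the
  asymmetry is what lets the t-scored central bias grow toward the obliques
  rather than being cancelled by the accompanying rise in residual noise.
- **Duration.**  Both encoding noises scale by (500/τ)^0.25 — a *common*
  factor, so cue reliabilities and hence the central bias are
  duration-invariant while precision improves with exposure.  The sublinear
  exponent keeps encoding noise inside the linear regime of the orientation
  circle (a square-root law would push foveal noise to ~27° at 100 ms,
  where wrapping attenuates fitted weights) and yields error-SD changes of
  realistic size across 100–1000 ms.

What the generator does *not* emulate: lapses and guessing mixtures, eye
movements, attentional fluctuations, spatial correlations in encoding
noise, left/right or up/down asymmetries (no generative leftward/upward
bias), and learning or serial dependence across trials.  Passing tests
therefore show that the pipeline recovers what these idealised observers
put in — not that human data will be as clean.

## Oblique-effect analyses

Sliding windows of width 20° step along the folded axis at 5° spacing
(overlap smooths the curve; the width follows the analysis convention, the
step is a package choice).  A trial joins a window if its folded ensemble
mean lies within the half-width, with reflection at 0 and 90 (both ends are
cardinals).  Windows with fewer than 30 kept trials per subject are flagged
missing, never zero.  Per subject and window an SWM is fitted and the
central bias and error SD recorded; the bias slope is the per-subject OLS
slope against distance-from-nearest-cardinal (0 → 45), tested across
subjects with a two-sided one-sample t and Cohen's d.

The close/mid/far analysis keeps trials whose folded mean is within
45 ± 10°, bins each subject's trials by per-subject tertiles of the target
element's distance to the nearest oblique, fits an SWM per bin (at least 26
trials per bin or an error suggests widening the inclusion window), and
submits the subject × bin biases to a one-way repeated-measures ANOVA.
Tertile boundaries are per-subject because the distance distribution is
subject-specific; the close/mid gap is intrinsically small relative to bin
noise (the middle bin differs from the first by a fraction of the group
SE at any realistic trial count), so conclusions rest on the far-vs-close
contrast and the ANOVA, not on a strict three-way sort.

## Serial-position analyses

Ranks come from onset times with competition ranking (ties share the
minimum rank).  Errors are z-scored within subject (sample SD) before
pooling, so precision differences do not re-weight subjects; deviations
stay in degrees.  For location L and window start r ∈ {1 … 23}, an SWM is
fitted to the pooled trials where L's rank lies in [r, r+2] (the other
elements' ranks vary freely) and the weight of L extracted; cells with
fewer than 30 trials are missing.  The 23-window count follows from 25
ranks and window 3 and is configurable.

Timecourse shape is compared across polynomial orders 1–4 by split-half
cross-validation: subjects are split in half 10,000 times (500 in the
fast validation runs), the timecourse re-estimated from the pooled training
half, each order fitted on centred window indices (reducing collinearity
between orders), and predictions correlated with the test-half timecourse.
Splits with constant test timecourses are skipped and counted; constant
predictions score r = 0.  The winning order maximises the mean test
correlation.

Cross-condition prediction fits weights on k = 5 folds of the training
condition and correlates X·ŵ with observed single-trial errors — on the
held-out fold when predicting the training condition itself, on all trials
otherwise — against a chance band (median, 1st/99th percentiles) from
shuffling observed errors.  Estimating 25 weights needs on the order of
300 training trials per condition for the transfer to rise above the band.

## Pipeline and reproducibility

`swmap run` executes the stage sequence for a study kind from one YAML
config with a mandatory seed; each stochastic stage draws from its own
substream (SeedSequence spawn keys), so toggling one stage never shifts
another's randomness, and re-runs are bit-identical (the report manifest
lists every artifact with its SHA-256).

## Problem sizes used in the validation runs

Solver–oracle agreement: 100 random full-rank 200×25 designs.  Profile
recovery: five replicate studies of 20 subjects × 400 trials (σ = 15, the
level at which regressor variance makes r > 0.9 recovery attainable; the
Monte-Carlo mean over replicates estimates the expected correlation with
five-fold less seed sensitivity).  Null calibration: 300–500 replicate
8-subject studies with 1,000 permutations.  Condition studies: 16 subjects
× 400 trials.  Serial studies: 10 subjects × 300 trials with 500 CV
splits.  Oblique study: 15 subjects × 800 trials (the binned fits need
~60 trials per bin to leave meaningful residual df for 25 coefficients).

## Known limitations

The SWM is a linear approximation to circular data; at large ensemble σ or
encoding noise, wrapping mildly attenuates weights (scale-invariant
quantities like correlations and t-contrasts are unaffected).  The IQR
fence is distribution-dependent and not idempotent by construction.
Permutation inference assumes within-subject exchangeability of locations
under the null; heteroscedastic location noise would distort it.  The
close/mid/far ANOVA treats bins as categorical and ignores the continuous
distance information.  Polynomial model comparison with few subjects is
sensitive to chance curvature shared across subjects; order selection
stabilises only once the generative modulation clearly exceeds per-cell
estimation noise.
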