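# Methods

## The tuning model

Numerosity *n* is represented by a Gaussian tuning curve on a linear
number line, mean *n* and standard deviation *w·n*.  The proportional
spread (scalar variability) produces the two classic signatures the
package's tests assert: for fixed *w* the peak height `1/(√(2π)·w·n)`
falls with *n*, and the overlap of consecutive numerosities grows with
*n* (the size effect).  The width *w* is dimensionless; the published
group estimates used for generator calibration are 0.094 (dice), 0.241
(canonical), and 0.276 (random), i.e. structured arrangements are coded
more precisely than random ones.

### Width estimation

`GaussianTuningModel` predicts each classification-error value by
`scale · f(probe; reference, w)` and minimizes the summed squared residual
jointly over all curves of one arrangement — one *w* per arrangement, the
convention the similarity analysis reports.  Numerical choices:

- **Optimizer.** Levenberg–Marquardt (scipy `least_squares`) on
  `log w` (and `log scale`), which enforces positivity without bounds.
  Start value 0.4, SSE-change tolerance 1e-8, at most 500 function
  evaluations; hitting the cap sets `converged=False` instead of raising.
- **Scale.** The bare density can exceed 1 for small *w·n* while a
  classification error is bounded by chance (~0.5), so a free
  multiplicative scale is fitted by default; `fit_scale=False` restores
  the literal density.  Whether the original analysis included such a
  factor is not stated; fitting it makes the estimator usable on any
  error scale, and noise-free self-consistency tests confirm it does not
  bias *w*.
- **Diagonal.** Self pairs (probe = reference) are excluded: a two-class
  decoder on a condition against itself is undefined.  An option appends
  them at a fixed chance error for sensitivity analyses.
- **Degenerate input.** A flat curve with the scale fixed carries no
  information about *w*; the fit returns `converged=False` rather than an
  arbitrary estimate.
- **Subitizing and estimation ranges** are fitted jointly within an
  arrangement (a single *w* governs both); the similarity data themselves
  decide how well one width serves the whole range.

The tests compare the optimizer against an independent dense grid search
(step 1e-4, scale profiled out in closed form); agreement is required to
1e-3 on noisy curves and 1e-6 noise-free.

## Pairwise decoding

Similarity between two conditions is 1 − cross-validated accuracy of an
L2-penalized logistic regression (penalty strength 1.0) on standardized
voxel features, stratified 5-fold, scaler fitted on training folds only.
The penalty is required because voxel counts can exceed exemplar counts;
folds shrink to the smaller class size when exemplars are scarce.  Group
matrices are plain means of subject-level error matrices.
Cross-arrangement pairs are computed when requested, but only
within-arrangement entries feed the similarity curves, which is how the
per-arrangement widths are defined.  Patterns are pooled over a single
bilateral mask; the data model retains hemisphere only for the amplitude
analysis.

## Amplitude and behavioral slopes

Both analyses are two-stage summary statistics, replacing mixed-effects
models with a per-subject OLS slope of the response (PSC, or log RT of
correct trials) on cell-centered numerosity within each
(arrangement × range) cell, followed by group mean ± SE and sign-flip
permutation inference.  For balanced designs the two stages agree in
expectation with a mixed model's fixed effects, while staying
assumption-light and fully testable.  Conventions:

- Subitizing is numerosities 2–4, estimation 5–8 (dice: 5–6).
- Centering is within (arrangement × range) over the records present, so
  each cell's centered covariate has mean zero; slopes are invariant to
  per-cell constant shifts, which the tests assert.
- Hemispheres are pooled by default (equivalent to averaging
  hemisphere-wise slopes under balance); a flag splits them.
- The discontinuity test pairs each subject's estimation and subitizing
  slopes, takes the difference, and flips signs: 10 000 permutations by
  default with the add-one correction `p = (1+k)/(1+B)`, so p is never 0
  and the test is exactly valid (super-uniform) under the null.

## Behavioral processing

RT trimming drops error trials, responses faster than 200 ms, then
log-transforms and removes trials whose residuals — from a per-subject fit
with one intercept per cell plus a common centered-numerosity slope —
exceed ±3 SD after global standardization.  The residual step iterates to
its fixed point: removing an outlier shrinks the residual SD and can
expose another, so a single pass would not be idempotent, whereas the
fixed-point version provably is (re-trimming removes nothing).  At
generator defaults the whole pipeline removes ~6% of trials, under the
10% bound the design anticipates.

Error summaries pool trials within (arrangement × range) and report
log-odds; zero-error cells get a 0.5-count continuity correction
(`odds = (errors+0.5)/(correct+0.5)`) so summaries stay finite — near-zero
error cells are common in the subitizing range, where slope estimation on
errors is not attempted.  Because trimming removes error trials, the
summary function takes the full trial table for error rates and
(optionally) the trimmed subset for log-RT means.  RT means are taken on
the log scale and back-transformed with `exp` (a geometric mean); error
log-odds back-transform through the inverse logit.

One calibration value deserves a flag: the published canonical-estimation
RT slope is printed as 0.010 with SE 0.015 and z = 4.06, which are
mutually inconsistent (likely a typo in one of the three).  The generator
uses the printed slope 0.010 and does not attempt to reconcile the
triplet.  Printed "ms" units on log-scale quantities are treated as
log-ms throughout.

## The synthetic generators

The generators produce data with exactly the structure the analyses
assume — they are the package's test bed, not a simulation of raw fMRI.

**Voxel patterns.**  Each voxel draws a preferred numerosity log-uniformly
on [1, 10] (uniform coverage on a compressive number line) and responds to
numerosity *n* with the normalized tuning density of width
*w*·preference, times a gain, plus i.i.d. Gaussian noise.  Using the
normalized density (taller peaks for narrower widths) is what links the
width parameter to decodability: narrow-width arrangements produce
selective, well-separated patterns, wide ones produce flat, confusable
patterns.  Defaults: gain 1.0, noise SD 0.7, chosen so adjacent-numerosity
decoding accuracies land in the 60–90% band typical of numerosity MVPA —
informative rather than saturated at either ceiling or chance.  The map
from generator *w* to recovered *w* is monotone but not the identity
(decoding error is not an affine function of curve overlap), so recovery
tests assert ordering and approximate magnitude, not equality.

**PSC records.**  `psc = cell_mean + slope·centered_n +
subject_intercept + noise`, with cell means/SDs and per-cell slopes set to
the published values, subject-intercept SD 0.08, and residual SD chosen so
the total matches the published cell SD.

**Behavioral trials.**  336 trials per subject balanced over the 19
conditions (remainder assigned to a seed-deterministic condition subset),
split into two runs.  Correctness is Bernoulli with cell log-odds plus a
subject intercept (SD 0.3); RTs are log-normal around the cell log-mean
plus slope·centered_n and a subject intercept (SD 0.12), residual SD 0.25
on the log scale.  1% of trials are replaced by fast guesses uniform on
[50, 200) ms so the trimming path is exercised.

Everything regenerates bit-identically from (config, seed); ground truth
(config plus sampled voxel preferences) is retained.

### What the generators do not emulate

No hemodynamics, autocorrelated noise, voxel-to-voxel covariance,
session/run effects, learning or fatigue, or eye movements.  Passing
recovery tests therefore show that the estimators are correct under the
model's own assumptions, not that real IPS data satisfy those
assumptions.

## Simulation sizes

Full-scale defaults mirror the study design (24 subjects, 200 voxels, 12
exemplars per condition).  The repeated-pipeline checks (50-seed width
ordering) run a reduced design — 4 subjects, 100 voxels, 24 exemplars,
within-arrangement pairs only — sized for statistical power per unit
compute: the variance of a decoding-accuracy estimate scales with
1/(subjects × exemplars) while runtime is dominated by per-decode
overhead, so fewer subjects with more exemplars are the efficient
allocation.  Slope-recovery and permutation-calibration checks use the
full-scale design (they are cheap).

## Known limitations

- One width per arrangement: no test of whether subitizing and estimation
  ranges, or individual subjects, differ in *w*.
- The discontinuity analysis assumes the subitizing boundary at 4 rather
  than estimating a breakpoint.
- Group inference is over subjects only (fixed stimulus set), matching
  the original design but limiting generalization over stimuli.
- The logistic-regression decoder is linear; nonlinear pattern
  differences would be read as similarity.
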