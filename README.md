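# numtuning

Analyses of how set size and spatial arrangement shape the neural coding of
non-symbolic quantities in the intraparietal sulcus (IPS), for researchers
working with ROI voxel patterns, percent-signal-change amplitudes, and
enumeration behavior.

Visual quantification splits into two regimes: *subitizing* — fast,
near-errorless enumeration of up to four elements — and *estimation* — the
approximate judgment of larger sets.  The approximate number system models
the estimation regime with overlapping Gaussian tuning curves on a linear
number line whose spread grows proportionally with numerosity (scalar
variability).  The tuning density of numerosity *n* at probe *x* is

    f(x; n, w) = 1 / (√(2π)·w·n) · exp( −(x − n)² / (2 (w·n)²) )

where the dimensionless width *w* indexes the precision of the
representation: small *w* means sharply separated curves, large *w* means
heavy overlap.  The package estimates *w* per stimulus arrangement
(random, canonical, and dice dot patterns) from *classification-error
similarity curves*: every pair of conditions is decoded with a
cross-validated ridge-penalized logistic regression on voxel patterns, and
1 − accuracy serves as the similarity between the pair.  Around that core
it provides

- `tuning` — the density, a curve-overlap statistic, and a
  Levenberg–Marquardt width estimator (`GaussianTuningModel` →
  `TuningFit`, statsmodels-style);
- `rsa` — pairwise decoding, similarity matrices, per-arrangement
  similarity curves;
- `amplitude` — percent-signal-change slopes on cell-centered numerosity
  per (arrangement × range), the subitizing→estimation slope discontinuity
  (sign-flip permutation test), and range contrasts;
- `behavior` — RT trimming (absolute floor plus ±3 SD residual
  trimming), log/logit back-transforms, condition summaries, RT slopes;
- `simulate` — seeded generators for voxel patterns, PSC records, and
  behavioral trials, calibrated to published group-level values, with
  ground truth retained for recovery tests;
- a `numtuning` CLI (`simulate`, `decode`, `fit-width`, `amplitude`,
  `behavior`, `run-all`, `import-roi`).

## Worked example

Simulate voxel patterns whose tuning widths differ by arrangement
(dice 0.094 < canonical 0.241 < random 0.276), decode all
within-arrangement condition pairs, and estimate the widths back:

```python
import numtuning as nt

cfg = nt.GeneratorConfig(n_subjects=4, n_voxels=100, exemplars_per_condition=24)
sets = nt.generate_patterns(cfg, seed=1)
m = nt.similarity_matrix(sets, seed=1, pairs="within")
for arr in ("dice", "canonical", "random"):
    fit = nt.estimate_arrangement_width(m, arr)
    print(arr, round(fit.w_hat, 3))
```

```
dice 0.098
canonical 0.246
random 0.25
```

The dice width comes back close to its generating value and far below the
other two; canonical and random are close to each other (their true widths
differ by only 0.035) and recover in the right order in ~9 of 10 seeds.
Amplitude analysis on a simulated PSC dataset shows the subitizing →
estimation discontinuity for random arrangements:

```python
psc = nt.generate_psc(nt.GeneratorConfig(), seed=1)
res = nt.range_slopes(psc)
print(res.get("random", "subitizing").slope)   # -0.045  (flat/slightly negative)
print(res.get("random", "estimation").slope)   #  0.019  (rising)
d = nt.discontinuity_test(res, "random", seed=1)
print(d.delta_slope, d.p_value)                # 0.064, p = 0.0065
```

Back-transforms reproduce the link-scale bookkeeping used for published
summaries: `nt.logit_to_percent(-1.46)` → `18.85` (% errors) and
`nt.logmean_to_ms(6.82)` → `916.0` (ms).

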