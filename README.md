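# eegmark

A resting-state EEG biomarker battery for source-space group studies, with
the statistical and machine-learning scaffolding needed to evaluate it
honestly. The package targets researchers who have patch-level (cortical
parcel) time series — e.g. minimum-norm source estimates collapsed onto the
68 Desikan-Killiany parcels — and want to ask: *do any of these biomarkers,
alone or in combination, distinguish two groups of subjects?*

## What it computes

Per recording, 3443 features across three domains:

* **Spectral** — multitaper band power (absolute and relative, five
  canonical bands: δ 1.25-4, θ 4-8, α 8-13, β 13-30, γ 30-48 Hz),
  hemispheric asymmetry, theta/beta ratio, peak alpha frequency, and the
  aperiodic exponent χ of the 1/f background (PSD ∝ f^-χ after removing
  oscillatory peaks).
* **Criticality** — detrended fluctuation analysis (DFA) exponents of the
  band amplitude envelopes (0.5 = uncorrelated, > 0.5 = persistent
  long-range temporal correlations), and the functional
  excitation/inhibition ratio fEI = 1 − corr(wA, wF) over envelope windows
  (≈ 1 near criticality).
* **Connectivity** — coherence, imaginary coherence, phase locking value
  (PLV = |⟨e^{i(φx−φy)}⟩|), weighted phase lag index (wPLI) and
  orthogonalized power envelope correlations (PEC) for all patch pairs,
  collapsed to 76 region-level connections per band and measure.

Around the battery: an age screen (per-feature Pearson correlation with age,
BH-FDR within feature type, linear detrending of flagged subgroups),
univariate group statistics (permutation test on means, Levene's test on
variances, FDR within type), and a repeated stratified **two-layer
cross-validation** framework — mRMR feature selection and hyperparameter
tuning confined to inner folds, generalization measured once per outer fold
as balanced accuracy (classification) or nMAE (regression). The two layers
exist because single-layer validation scores are systematically optimistic
when p ≫ n; the framework makes that gap visible instead of reporting it as
performance.

Because such cohorts are rarely public, `eegmark.synth` generates
reproducible synthetic cohorts — 1/f^χ backgrounds, band oscillations with
controllable peak frequency, fGn-modulated envelopes with a target Hurst
exponent, phase-lagged patch coupling, realistic metadata, and injectable
age trends and group effects — storing the realised ground truth with every
recording so each estimator's recovery can be tested.

## Worked example

`examples/04_connectivity.py` generates three two-patch subjects with
controlled alpha-band coupling and prints all five measures:

```
case                      Coh  Imcoh   wPLI    PLV    PEC
zero-lag, kappa=1       1.000  0.000  0.082  1.000 -0.021
90 deg lag, kappa=1     1.000  1.000  1.000  1.000  1.000
uncoupled (kappa=0)     0.061  0.034  0.066  0.064  0.003
```

The first row is the classic volume-conduction signature: a shared zero-lag
signal saturates coherence and PLV while the lag-sensitive measures (Imcoh,
wPLI) correctly stay near zero — exactly the contrast these measures were
designed for. At a quarter-cycle lag every phase measure saturates, and
uncoupled patches sit at the chance floor.

The other examples cover cohort simulation (`01`), spectral biomarkers
(`02` — recovers an injected 9.5 Hz peak and the 1/f exponent), criticality
(`03` — DFA tracks the injected Hurst exponent), and the full
simulate → features → stats → predict pipeline (`05`), which is also
available as a thin CLI:

```bash
eegmark --config run.json --seed 1 --out my_run
```

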