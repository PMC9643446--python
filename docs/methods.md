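# Methods

`eegmark` implements a resting-state EEG biomarker battery on source-patch
time series, together with the statistical and predictive machinery needed to
ask whether any of those biomarkers separates two groups. Because cohorts of
this kind are rarely shareable, the package ships a synthetic-cohort
generator with controllable ground truth for every estimator; all validation
in the test suite runs against that generator.

## Signal model of the generator

Each subject is a `patches x samples` array. Per patch the signal is

    x(t) = b * n_chi(t) + sum_bands a_band * o_band(t)

where `n_chi` is unit-variance Gaussian noise spectrally shaped to
`PSD(f) ~ f^-chi` (FFT filter `|H(f)| ~ f^(-chi/2)`, gain flattened below
0.5 Hz to avoid the DC pole; the analysis range starts at 1.25 Hz so the
floor is invisible), and each oscillation `o_band` is unit-RMS and one of:

* **band-limited Gaussian noise** — boxcar spectral shape with 10%
  raised-cosine edges (non-alpha bands), or a Gaussian spectral shape
  centred on the configured peak frequency (alpha);
* **an amplitude-modulated narrow line** when the band has a target Hurst
  exponent H: a sinusoid with Brownian phase (Lorentzian line, FWHM = 1/4 of
  the peak bandwidth) multiplied by the envelope
  `max(1 + 0.35 * fGn_H(t), 1e-6)`, with the fractional Gaussian noise drawn
  exactly by Davies-Harte circulant embedding.

Two construction details matter and were chosen deliberately. First, the
envelope is an offset-and-clipped fGn rather than a rectified one: taking
`|fGn|` squares the autocorrelation and collapses the injected long-range
structure towards DFA 0.5, whereas the offset form preserves H (clipping is
a > 2.8 sigma event and negligible). Second, LRTC bands use a
deterministic-envelope carrier (the phase-diffusing sinusoid) instead of
filtered noise, because a noise carrier superimposes its own Rayleigh
envelope (DFA 0.5) on the injected modulator and biases envelope DFA
downward. The narrow linewidth keeps the Lorentzian tails inside the
analysis band; wider lines lose tail power at the band edges, which
re-enters the envelope as fast fluctuations and again pulls DFA towards 0.5
(measured bias at FWHM = bandwidth/2 was about -0.04; at bandwidth/4 it is
within the +-0.05 recovery tolerance).

Coupled patch pairs share a common band component mixed as
`sqrt(1-kappa^2) * private + kappa * common`, the common copy phase-shifted
by the configured lag via its analytic signal. `kappa = 1` at zero lag
reproduces the volume-conduction signature (coherence and PLV saturate,
Imcoh and wPLI stay at the floor); a quarter-cycle lag saturates all phase
measures.

Cohort metadata: ages are truncated normals on [18, 55] (group means/SDs
default to 32.3 (12.3) and 43.7 (9.0) years for the comparison and clinical
group respectively), sex is Bernoulli (57%/54% female), and AQ/SPQvis/SPQaud
are per-group normals (AQ 51.0 (10.1) vs 85.7 (9.9); SPQvis 10.5 (3.0) vs
7.1 (3.2); SPQaud 9.1 (2.5) vs 6.7 (2.5)). Default cohort sizes are 91 + 95.
Linear age trends and additive group effects (Cohen's d on a named generator
parameter, realised as `d` times that parameter's between-subject SD added
to the clinical group's mean) are injectable; the realised per-subject
parameters are stored with each recording so recovery tests can regress
estimates on truth.

## Preprocessing

Zero-phase FIR filtering throughout (Hamming window, transition width 25% of
the lower band edge, length capped at a third of the signal), applied as a
single convolution with the filter's autocorrelation — exactly equivalent to
forward-backward filtering for a linear-phase kernel, with odd-reflection
padding. Phase linearity matters because PLV, Imcoh and wPLI sit downstream.
Resampling is polyphase (`resample_poly` with the rational rate). Recordings
are cut into non-overlapping 4 s epochs (trailing partial epoch dropped);
subjects with under 2 minutes of signal are excluded, the boundary kept.

Vertex-to-patch collapse aligns polarities before averaging: within a patch,
each vertex's sign relative to the patch's first principal temporal
component is computed, the principal component is oriented with the pre-flip
majority (ties orient with the first correlated vertex, zero correlation
means no flip), minority vertices are negated, and amplitudes averaged.

Temporally extended estimators (envelopes for DFA/fEI, PLV, PEC)
concatenate epochs first. 0.5 s of signal is discarded at the edges and
around every *non-contiguous* epoch join (tracked via epoch onsets); joins
between epochs that were adjacent in the recording are seamless and are not
trimmed — trimming every 4 s boundary would discard a quarter of the data
for nothing.

## Feature battery (3443 columns)

| family | count | definition |
|---|---|---|
| power (abs + rel) | 680 | multitaper PSD integrated per band; relative = fraction of 1.25-48 Hz power |
| theta/beta ratio | 6 | per-patch theta/beta, averaged per region, hemispheres pooled |
| asymmetry | 30 | right-minus-left absolute power per homotopic pair, averaged per region |
| peak alpha frequency | 69 | per patch + one global fit on the patch-averaged PSD |
| aperiodic exponent | 68 | negative log-log slope after peak removal |
| DFA | 345 | (68 patches + global mean) x 5 bands |
| fEI | 345 | likewise |
| connectivity | 1900 | 5 measures x 5 bands x 76 region connections |

Spectra are DPSS multitaper estimates on 4 s epochs with 1 Hz half-bandwidth
(7 tapers), normalised so the one-sided density integrates to the signal
variance. Band integrals use half-open bins `[f_lo, f_hi)` so the five bands
tile 1.25-48 Hz exactly and the relative powers are a partition of unity;
the same range is the relative-power denominator. Asymmetry uses absolute
power. The six theta/beta values pool hemispheres — the only pooling
consistent with six regions.

The aperiodic/peak decomposition is a self-contained fixed-mode (no knee)
spectral parametrization: (1) a robust log-log line (refit after discarding
points more than 1 SD above the first fit — peaks only push residuals up);
(2) iterative peak extraction, detecting on the log residual (threshold 2 SD,
at most 6 peaks, Gaussian SD bounded to [0.25, 6] Hz) but *refining on the
linear residual* via a weighted parabola on its logarithm — the log of a
Gaussian is an exact parabola, so a peak additive in power is recovered
without the centre skew that log-space Gaussian fitting inherits from the
sloping background; (3) a line refit on frequencies further than 3.5 peak
widths from any peak; chi is the negative refit slope. PAF is the centre of
the highest peak inside 8-13 Hz, falling back to the argmax of the flattened
spectrum there so the feature matrix never has holes. Known limitation: with
strong oscillations the unmodelled skirts (Lorentzian tails, boxcar band
plateaus) bias chi low by up to ~0.3; recovery within +-0.15 holds on
oscillation-free spectra, and the bias is common to both groups so the null
machinery is unaffected.

DFA: demeaned-envelope cumulative sum, 12 log-spaced window sizes in the fit
range (default 2-20 s; tests on short recordings use 2-10 s), 50% overlap,
per-window linear detrend, fluctuation = mean window RMS, exponent =
least-squares log-log slope. fEI: non-overlapping windows (default 5 s),
per-window mean amplitude wA and SD of the detrended cumulative sum of the
wA-normalised envelope (wF); fEI = 1 - corr(wA, wF), flagged invalid when
the band's DFA exponent is below 0.6 but never removed from the table (the
column contract stays intact).

Connectivity: Coh and Imcoh from the epoch-and-taper-averaged coherency;
Imcoh is stored as |Im C| so signed values cannot cancel under region
averaging (and every matrix is symmetric). wPLI is the Vinck estimator
without debiasing, 0/0 defined as 0 with a relative tolerance (a purely
real cross-spectrum leaves only float noise in the imaginary part). PLV is
computed on all concatenated samples. PEC orthogonalizes each signal against
the other samplewise (`Im(y_a conj(x_a)/|x_a|)`), Pearson-correlates log
power envelopes (amplitude floor 1e-12), and averages the two directions;
`y = c x` gives 0 by convention. The 68x68 matrices collapse to 76 region
connections: 66 pairs of the 12 (region, hemisphere) nodes plus 10
intra-node averages over distinct patch pairs — the single-patch insular
nodes have none.

## Age screen, group statistics, prediction

Every feature's Pearson correlation with age is tested (t distribution,
n-2 df) with BH-FDR applied within each of the 12 feature types (absolute
and relative power count as one type). A type is flagged when more than 5%
of its features are significant at adjusted p < 0.05; the flag is refined to
(family x band) subgroups by the same rule, and flagged columns are replaced
by their whole-cohort OLS residual plus the original column mean (pooling
groups is deliberate: detrending within group would remove part of any true
group difference; re-adding the mean keeps features on their native scale
for mRMR and regularized models). The operation is idempotent and leaves
detrended columns with exactly zero age correlation.

Group comparisons use a two-sided permutation test on the absolute mean
difference (exhaustive when all label arrangements fit in the permutation
budget, otherwise Monte-Carlo with the add-one estimate p = (b+1)/(n+1)) and
classic Levene's test (mean-centred; median centring available) — both
FDR-corrected within type at alpha 0.05.

Type-level significance uses the same >5% convention as the age screen: a
biomarker type is declared significant when more than 5% of its features
survive within-type FDR. The distinction matters for calibration: under a
global null, BH's probability of at least one rejection per type equals
alpha (Simes' identity), so isolated single-feature rejections occur in
roughly one type per two null cohorts and carry no type-level evidence; the
>5% rule restores a usefully small type-level false-positive rate. Its
irreducible floor is the small, internally correlated types — the six
theta/beta ratios all track the subject's 1/f exponent, so they behave as
one effective feature and the type flags in about 5% of null cohorts no
matter the cohort size. Two further caveats: the rule's thresholds depend on
the family cardinalities, so calibration statements assume the full
68-patch battery; and the mean-centred Levene test is anti-conservative
(empirically ~12% at alpha 0.05) on heavy-tailed ratio features — the
median-centred (Brown-Forsythe) variant is available where that matters.

Prediction is a repeated, stratified, two-layer CV: outer folds are touched
exactly once per model for the generalization estimate; inner folds
grid-search mrmr_k x hyperparameters. Standardization, mRMR and any
model-specific selection are refit inside each training partition — an
instrumentation test asserts that perturbing a fold's test subject never
changes that fold's fitted model. mRMR is greedy with F-statistic relevance,
mean |Pearson r| redundancy and quotient scoring, run per feature type with
the union pooled (this is what neutralizes the 1900-vs-6 family imbalance);
features perfectly correlated with a selected one are skipped. Models:
linear-kernel SVM with RFE, L2 logistic regression with sequential forward
selection (capped at 20 steps, early stop on no training-score improvement),
L1 logistic regression, random forest, and L1/L2 linear regression for the
questionnaire scores. Grids: mrmr_k in {10, 20, 30, 40}; 16 log-spaced C in
[0.01, 1000] (logistic, mirrored as 1/C for the regression alphas); 13
log-spaced C in [0.001, 1] (SVM); trees {10, 50, 100, 500, 1000} x depth
{1, 2}. Validation ties break towards smaller mrmr_k, then stronger
regularization. A fully shrunk lasso predicts the majority class (or the
training mean) rather than raising. Scores: balanced accuracy for
classification, nMAE for regression; one-sided Wilcoxon signed-rank against
0.5 / 1.0 over the outer folds (needs at least 6 folds).

## Problem sizes and numerical defaults

The package defaults reflect full-scale recordings (300 s at 500 Hz, 68
patches, 10 x 10 x 10 CV, 10,000 permutations). The test suite and the
acceptance script exercise the identical code paths at validation sizes
chosen per purpose: estimator-recovery checks use the durations the
estimators need (300 s for DFA, 120 s for spectral fits); the column
contract, the 20-seed null calibration and the validation-test gap run the
full 68-patch battery on short recordings (16-24 s at 128 Hz, DFA fitted on
1-4 s, fEI windows of 1.5 s, 9,999 permutations, reduced grids — mrmr_k
{10, 20}, 4-6 C values — in repeated 5-by-5 two-layer CV); sensitivity to
an injected d=2 group effect uses a 120-subject cohort on a 14-patch
homotopic atlas subset, large enough that the cross-validated accuracy
measures pipeline quality rather than small-sample noise (d=2 on the latent
amplitude caps balanced accuracy at about Phi(1) = 0.84). A 48 s / 160 Hz
scale serves the remaining integration fixtures.

## What the generator does not emulate

No sensor space, volume conduction or inverse modelling (inputs are already
patch signals); no artifacts (blinks, ECG, movement) and hence no rejection
interacting with the duration rule; no spatial autocorrelation beyond the
explicitly coupled pairs; oscillation parameters are chosen for estimator
validation power, not biological realism. Passing tests therefore
demonstrate that the estimators recover what they claim to measure and that
the statistical machinery is calibrated — not that any particular biomarker
separates real clinical groups.

## Other limitations

* chi estimates under strong oscillations carry the skirt bias noted above.
* fEI's validity rule is reported but not enforced in the table; downstream
  consumers can filter on the DFA exponent if they wish.
* The permutation and CV machinery assumes exchangeable subjects; no
  site/batch structure is modelled.
* Imcoh-as-magnitude discards the sign of the lag; signed region averages
  would require a directionality convention the region collapse does not
  define.
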