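# Methods

## Model and estimation

The core object is a structural vector autoregression over k standardized
ROI series with an instantaneous coefficient matrix A(0) whose diagonal is
structurally zero:

    X(t) = A(0) X(t) + Σₙ A(n) X(t−n) + E(t),   n = 1…p.

Each target equation i is estimated by ordinary least squares of x_i(t) on
the other series at lag 0 and on all series at lags 1…p, plus an intercept
(kept for numerical safety, not counted as a model parameter).  This is the
model exactly as written; the estimator is deterministic and reproducible.
It carries the usual simultaneity property of structural regressions:
whenever the zero-lag-purged residual series remain temporally predictable,
the projection places nonzero mass on lagged cross terms even without true
lagged coupling.  This is documented behavior, not corrected (see
Limitations).

Causal strength is summarized as CPGC_ij = Σₙ a_ij(n)², diagonal zero.  A
variant normalizing row i by the target equation's residual variance is
available (`normalize_by_resid`) and off by default.  The off-diagonal of
A(0) is exposed as the instantaneous-association matrix, optionally
symmetrized.

Model order defaults to 5; BIC selection over 1…p_max is available, with
BIC = T′·log det Σ̂ + n_free·log T′ computed on each candidate's own
effective sample and ties broken toward the smaller order.  Standardization
(mean 0, sample SD 1 per column) is mandatory before fitting unless
explicitly overridden; fits require T − p > k(p+1).

## Surrogate inference

Null distributions per directed path come from phase-randomized surrogates:
each column's FFT phases are replaced by uniform draws (DC and Nyquist bins
untouched), preserving each series' magnitude spectrum — hence power
spectrum and autocorrelation — while destroying all cross-series structure,
lagged and instantaneous.  Each surrogate set is standardized and refitted
with the same model.  Surrogates are generated per subject and each
subject's observed CPGC is ranked within that subject's own null
(respecting subject-specific spectra), with the add-one rule
p = (1 + #{null ≥ obs}) / (1 + n) so p is never zero.  Group-level
within-group significance combines the m subjects' p-values with Fisher's
statistic −2Σ log p against χ²(2m), thresholded at α = 0.01 by default; no
correction across the k(k−1) paths is applied at this stage (a
Benjamini–Hochberg option exists in the API, off by default).  Pairs
significant in both directions are classified bidirectional, in one
direction unidirectional.

The default surrogate count is 10,000.  Test- and script-scale runs use
500, which bounds the per-subject p at 1/501 — small enough for the Fisher
combination across 16 subjects to resolve group effects.

## Group contrasts, behavior and QC

The between-group test per path is a linear model
`value ~ intercept + group + atrophy` with group coded 0/1 — equivalent to
a one-way ANCOVA for two groups, no interaction term.  The group effect is
reported as F = t² with its two-sided p; a covariate with zero variance is
dropped, reducing the model exactly to the one-way ANOVA.  The atrophy
covariate is one scalar per subject (a gray-matter index); the synthetic
generator fabricates it directly with a configurable group shift.

"Increased" paths are those with patient > control at α = 0.01 intersected
with the within-patient significant mask; "decreased" paths are
control > patient intersected with the within-control mask.  Behavior
correlations (Pearson r, exact t-transform p with n−2 df) are computed only
for paths surviving that masked contrast, within the patient group.  Motion
QC correlates each subject's mean framewise displacement with every path;
FD per frame is the sum of absolute translational differences plus
rotational differences converted to arc length on a 50 mm sphere, with
FD₁ := 0 and the mean taken over all frames including the first.

## Preprocessing conventions

Band-pass filtering is an ideal frequency-domain mask (bins with
low ≤ f ≤ high retained, 0.01–0.08 Hz by default): deterministic, exact at
any length, no filter-order ambiguity.  Nuisance regression residualizes on
an intercept, a linear drift term, the six motion parameters, supplied
WM/CSF columns, and optionally a measured whole-brain average
(global-signal regression, off by default to match the primary analysis;
when no measured global series is supplied the mean of the ROI columns is
used, which is only sensible at large k).  Standardization uses the
sample (T−1) convention.  Volume accounting: a 478 s scan at TR 2 s minus
10 equilibration volumes leaves 229 analysis frames.

ROI geometry: 33 nodes from four resting-state networks, shipped as a
coordinate table; masks are closed balls (voxel-center Euclidean distance
≤ radius, default 12 mm) intersected with a brain mask on the target grid.
The three nodes shared between DMN and HCMN (PCC, both posterior IPLs) are
kept as distinct ROIs with distinct centers.  No stereotaxic-frame
conversion is performed; coordinates live in whatever frame the grid affine
defines.

## Synthetic cohorts

The generator emulates the study's data structure: two groups × 16 subjects
× 229 frames at TR 2 s.  "Neural" signals follow a structural VAR whose lag
tensors carry the planted edges; instantaneous correlation is induced by a
mixing matrix applied to the Gaussian innovations — never through A(0) in
generation — so "instantaneous correlation without causality" is
unambiguous ground truth.  Scenarios:

* `null` — independent white series.  Here observed data and surrogates are
  exchangeable, so surrogate inference is exactly calibrated; this is the
  reference for the calibration test.
* `instantaneous-only` — zero lagged coefficients, a shared innovation
  component giving every pair correlation 0.6 (a localized single-pair
  variant is available).  The purging test bed.
* `one-edge` — self-autoregression 0.3 in both groups; patients additionally
  get one lag-1 edge (default strength 0.5, jittered across subjects with
  SD 0.1), coupled to the MMSE-like score at target r = −0.6.

Optional dressing: canonical double-gamma HRF convolution (peak 6 s,
undershoot 16 s, ratio 6, sampled at TR, identical across nodes), linear
drift, a shared global component with a measured whole-brain proxy,
random-walk motion traces, AR(1) WM/CSF series.  Behavior scores are scaled
to group-typical means/SDs of the study instruments; coupled columns are
built as r·z + √(1−r²)·ε from the standardized realized edge strengths, so
the population correlation equals the target.  Atrophy covariates get a
patient-shift of −0.5 by default.  All randomness flows from one master
seed through named substreams; cohorts are bit-reproducible.

What the generator does not emulate: voxel-level image formation,
physiological (cardiac/respiratory) noise, variable HRFs across regions,
scanner drift spectra.  Passing tests therefore demonstrate the statistical
machinery under the stated generative assumptions, not robustness to every
property of real BOLD data.

## Scaled study conditions for the statistical tests

Cohort-scale properties are verified at k = 6 nodes, order 5, T = 229,
16 subjects per group, 500 surrogates — 20 cohorts for calibration, 50 for
recovery — with two deliberate deviations from the full preprocessing
chain, both chosen because the properties under test are otherwise
unmeasurable:

* **No band-pass before fitting.**  An ideal 0.01–0.08 Hz mask at T = 229
  keeps ~32 of 115 frequency bins; a 37-regressor autoregressive design on
  such narrowband data is close to collinear, coefficient variance explodes,
  and every path in every group tests "significant".  Filtering before
  autoregressive causality estimation is a known hazard; the scenario
  signals are already band-limited by construction, so the scenario
  analyses regress nuisance terms and standardize without filtering.
* **No HRF blurring in the calibration/recovery scenarios.**  At TR 2 s the
  hemodynamic overlap moves a 1-TR neural lag almost entirely into the
  instantaneous term (measured: the planted edge's A(0) entry rises to
  ≈ 0.19 while its CPGC drops to noise level), so no effect size makes a
  blurred lag-1 edge recoverable by a lag-based statistic at this sampling
  rate.  The HRF stays available in the generator for data-shape emulation.

The planted one-edge strength (0.5) was calibrated so that the full
pipeline detects the edge in ≥ 90% of cohorts at these dimensions, as the
scenario definition requires.

## Calibration: what holds and what cannot

Under the global null the within-group significant-path rate at α = 0.01 is
nominal (tested over 20 cohorts × 30 paths).  Under instantaneous
correlation the observed fit and the independence-destroying surrogate null
are *not* exchangeable, and two opposing mechanisms appear, both measured
during development:

* correlated source regressors make the observed lagged-coefficient
  variance larger than under the null (inflation; dominates when the
  correlation is confined to a pair of channels);
* the zero-lag terms shrink the observed residual variance relative to the
  null (conservatism; dominates under a shared global component).

With the default shared-component design at correlation 0.6 the purging
model is strictly conservative (0 significant paths in 600 group-level
trials) while the naive no-A(0) Granger variant declares ~80% of paths
significant — the purging contrast in its clearest form, and the safe
direction of miscalibration.  Fisher combination across 16 subjects
amplifies any per-subject non-exchangeability, so an exactly nominal rate
under visible instantaneous correlation is not attainable for this
estimator/null pairing; the corresponding acceptance check is left failing
by design rather than tuned.

## Other limitations

* Structural simultaneity: with temporally predictable purged residuals
  (e.g. smoothed data), true zero-lag correlation induces nonzero lagged
  cross-coefficients in the structural projection itself.
* Lag-based causality at TR 2 s cannot see sub-TR neural delays, and
  hemodynamic blurring absorbs 1-TR delays into A(0).
* Surrogate inference assumes stationary spectra; the ensemble preserves
  each series' spectrum exactly but no cross-structure.
* Demographic summary t-tests use the pooled-variance form by default
  (Welch behind a flag); the χ² test applies Yates correction when any
  expected cell count is below 5.
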