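# cpgc — correlation-purged Granger causality for resting-state networks

`cpgc` implements an effective-connectivity analysis for resting-state fMRI
ROI time series, of the kind used to compare directed (causal) inter-regional
influence between a patient group and matched controls — for example amnesic
mild cognitive impairment (aMCI) versus healthy elders across the default
mode, hippocampal-cortical memory, dorsal attention and fronto-parietal
control networks.  It is aimed at researchers who want a tested, scriptable
version of this pipeline together with a synthetic-cohort generator that
makes every statistical property of the method checkable.

## The model

For k standardized ROI series x₁…x_k stacked as **X**(t), the package fits a
structural (modified) multivariate autoregressive model with an
instantaneous coefficient matrix whose diagonal is constrained to zero:

    X(t) = A(0) X(t) + A(1) X(t−1) + … + A(p) X(t−p) + E(t),   diag A(0) = 0

The off-diagonal entries of A(0) absorb zero-lag cross-correlation, so the
lagged coefficients are purged of the leakage of instantaneous correlation
into lagged estimates that hemodynamic blurring otherwise produces.  Directed
causal strength from ROI j to ROI i is

    CPGC_ij = Σₙ a_ij(n)²,   n = 1…p   (default order p = 5, BIC optional)

Inference per directed path uses phase-randomized surrogates (magnitude
spectrum retained, phases randomized independently per series; 10,000 by
default), an add-one empirical p per subject, Fisher's method across the
subjects of a group (χ² with 2m df), and a p < 0.01 threshold with
bi-/uni-directional classification of pairs.  Between-group contrasts are
per-path one-way ANOVAs with a gray-matter atrophy covariate, masked by the
within-group significant paths; surviving paths are correlated (Pearson)
with neuropsychological scores (MMSE, CVLT recall conditions, CDT) and
checked against mean framewise displacement as a motion-QC control.

## Worked example

Simulate one synthetic patient whose ground truth contains a single planted
lag-1 edge (ROI 0 → ROI 1, strength 0.5) and estimate connectivity:

```python
import numpy as np
from cpgc import CorrelationPurgedGC, CohortConfig, make_ground_truth, simulate_subject

gt = make_ground_truth("one-edge", effect=0.5)
cfg = CohortConfig(hrf=False, drift_amplitude=0.0)
sub = simulate_subject(gt, "patient", cfg, np.random.default_rng(0))
est = CorrelationPurgedGC(order=5).fit(sub.series.data)
print(np.round(est.cpgc_, 3))
```

```
[[0.    0.024 0.009 0.024 0.008 0.078]
 [0.148 0.    0.015 0.018 0.012 0.009]
 [0.036 0.013 0.    0.026 0.013 0.022]
 [0.019 0.028 0.01  0.    0.017 0.008]
 [0.025 0.031 0.034 0.014 0.    0.029]
 [0.035 0.034 0.085 0.048 0.075 0.   ]]
```

Entry [1, 0] — the influence of ROI 0 on ROI 1 — is 0.148, an order of
magnitude above the background entries, which reflect finite-sample noise at
T = 229 frames.  A full cohort analysis (16 + 16 subjects) detects that edge
as a patient-increased path:

```python
from cpgc import simulate_cohort, analyze_cohort
cohort = simulate_cohort(gt, CohortConfig(hrf=False), seed=3)
res = analyze_cohort(cohort, n_surrogates=500, band=None, seed=1)
print(res.diff.increased)      # -> [(1, 0), (5, 0)]
```

Here the planted edge (1, 0) is recovered; (5, 0) is a spurious edge of the
kind the recovery tests bound at ≤ 1 per cohort on average.
`res.behavior` then holds the Pearson correlations between the surviving
paths' CPGC values and the patients' behavior scores (the generator couples
MMSE to the planted path strength at r = −0.6 by default).

The same pipeline is available stage-by-stage from the shell:

```sh
cpgc simulate --out-dir run --seed 3 --scenario one-edge --no-hrf
cpgc prep --out-dir run --no-bandpass
cpgc fit --out-dir run && cpgc null --out-dir run --n-surrogates 500 --seed 3
cpgc infer --out-dir run && cpgc group --out-dir run
cpgc correlate --out-dir run && cpgc report --out-dir run
cpgc --show-defaults     # every study default in one place
```

A 33-ROI coordinate table (12 DMN, 6 HCMN, 6 DAN, 9 FPCN nodes, 12 mm
spheres) ships with the package (`cpgc.default_roi_set()`), together with
sphere-mask construction and ROI extraction for volumetric data.

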