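# Methods

This note records the models implemented in `mobius_gate`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## The scientific setting

Epic dreaming — continuous, mundane, all-night dreaming recalled with
autobiographical confidence — is treated here as a failure of REM sleep's
containment of internally generated content. Two quantitative objects
follow from that framing:

1. a **REM Gating Integrity (RGI) composite** built from three oriented
   sleep-EEG features, used to compare small clinical groups, and
2. a **misbinding probability model**: a no-intercept logistic model of the
   chance that a simulated (dreamed) sequence is encoded as veridical
   memory.

Clinical polysomnography for this phenotype is governed by restrictive data
agreements, so the package ships a seeded synthetic generator that plays
the role of the cohort; all quantitative claims in the test suite are about
recovery of *known* ground truth, not about any real patient data.

## Synthetic sleep generator

**Hypnograms.** Stage sequences follow a first-order Markov chain over
{W, N1, N2, N3, REM}; bout durations are exponential with per-stage means.
The exponential/Markov pair is the simplest generator for which "mean bout
duration" is a sufficient statistic of REM continuity. Consecutive visits
to the same stage merge into one bout, and the final bout is truncated to
the requested total duration. Default stage means (W 90 s, N1 60 s,
N2 600 s, N3 480 s, REM 900 s) give plausible adult nights; they are
config-exposed, not claims about any cohort. Bouts live in continuous time;
no 30-s epoch grid is imposed.

**Coupled epochs.** An epoch is the sum of
- a unit-amplitude slow oscillation (SO), a 0.75 Hz cosine, so the
  analytic-signal phase is 0 at the SO positive peak;
- spindle bursts: 1-s Hann-windowed packets at the spindle-band centre
  frequency (13.5 Hz by default), at most one per SO cycle, occurring with
  probability 0.5, placed so the SO phase at the packet centre is a
  von Mises(`preferred_phase`, `kappa`) draw (`kappa = 0` gives uniform
  phases, i.e. no coupling);
- background noise with power spectral density proportional to
  `f**(-chi)`, realized by scaling rFFT amplitudes of white noise by
  `f**(-chi/2)`, normalized so the SO-to-noise RMS ratio equals `snr`
  (default 5).

The population mean resultant length of von Mises phases is the Bessel
ratio `I1(kappa)/I0(kappa)`; the generator exposes that map and its
numerical inverse so a target coupling vector length can be translated
into a concentration.

**Cohort feature tables.** Control subjects are drawn from Gaussians —
coupling on the *logit* scale (mean logit(0.45), SD 0.35), REM mean bout
15 ± 4 min, 1/f steepness 2.5 ± 0.5 — and "epic" subjects are shifted down
by `effect_size × SD` on each feature's drawing scale (default 1.0 SD per
feature, matching the ≈|1| standardized effects the composite analysis is
designed to resolve; group sizes default to 4 + 4). Drawing coupling on the
logit scale makes the downstream logit transform exactly
variance-stabilizing under the generative model. Negative bout durations
(possible in the Gaussian tail at large effect sizes) are clipped to zero
with a warning.

What the generator does **not** emulate: real spindle morphology and
density variation, stage-dependent spectra, artifacts, inter-night
variability, or any physiological link between the three features beyond
their (optional) correlation through the covariance of draws. Passing
tests therefore demonstrate *algorithmic correctness and statistical
calibration under the stated model*, not clinical validity.

## Feature extraction

- **SO phase**: 4th-order Butterworth band-pass (0.3–1.5 Hz,
  forward-backward), Hilbert transform, angle. Phase 0 = SO positive peak.
- **Spindle events**: band-pass 11–16 Hz, Hilbert envelope, 0.2-s moving
  average; events are runs exceeding mean + 1.5 SD of the envelope for at
  least 0.3 s, timestamped at the envelope peak, with the SO phase at that
  sample attached. The 1.5-SD default is calibrated to 1-s packets: a 2-SD
  threshold cuts the Hann envelope so high that supra-threshold runs fall
  under the 0.3-s minimum duration. With the default burst occupancy
  (~0.5 bursts per SO cycle) recall against injected ground truth is ≈0.96;
  back-to-back bursts (occupancy → 1) merge into single detections, which
  is a known detector limitation shared with threshold detectors generally.
- **Coupling**: mean resultant vector of event phases; R in [0, 1] plus the
  preferred phase. An empty event list is a *missing* feature, never 0.
- **1/f steepness**: Welch PSD (4-s Hann segments, 50% overlap), OLS of
  log10 power on log10 frequency over 30–45 Hz, returned as −slope. The
  band sits above sleep oscillatory peaks, so a plain OLS fit is unbiased
  without peak-aware spectral parameterization; at 5-min epochs the
  estimate's sampling SD is ≈0.1, well inside the ±0.2 recovery tolerance
  the tests assert. The statistic is invariant to rescaling the signal.
- **REM continuity**: arithmetic mean of REM bout durations in minutes;
  no REM bouts → NaN with a warning.

Bands (SO 0.3–1.5 Hz, spindle 11–16 Hz, fit 30–45 Hz) are common
sleep-EEG practice and config-exposed; nothing downstream depends on the
specific choices beyond the stated recovery tolerances.

## RGI composites

Per subject, the feature vector (logit coupling, REM mean bout, steepness)
is z-scored against the control group (mean/SD with n−1 denominators;
controls only — case rows never enter the reference). Orientation: larger
z ⇒ tighter gating on every component. Two scalar composites:

- `RGI_min = min(z1, z2, z3)` — a weakest-link summary: gating is only as
  intact as its loosest component. The min (rather than mean or a weighted
  score) is this package's design decision; it is deliberately
  conservative and is flagged as such wherever reported.
- `signed_distance = sign(mean z) * sqrt(z' Σλ⁻¹ z)` with
  `Σλ = (1 − λ) Σ + λ I`, λ = 0.20 fixed, and Σ the covariance of control
  z-vectors. Shrinkage bounds the smallest eigenvalue of Σλ below by λ, so
  the distance exists even with 4 controls (where Σ of 4 z-vectors in 3
  dimensions is singular or nearly so). Computing Σ on the z scale makes
  the distance a correlation-shrunk Mahalanobis distance. The mean-z sign
  rule (ties counted positive) is again a documented design decision: the
  magnitude alone cannot say whether a subject sits on the loose or tight
  side of the control cloud.

Logit clipping uses eps = 1e-6; coupling exactly 0 or 1 maps to ±13.8
rather than ±inf.

## Small-sample inference

All inference is designed for n = 4 per group:

- **Hedges' g**: pooled-SD standardized mean difference times
  J = 1 − 3/(4N − 9); at N = 8, J = 1 − 3/23 ≈ 0.8696.
- **Exact randomisation test**: all C(n1+n2, n1) group relabellings (70 at
  4/4), two-sided p = proportion of relabellings with |statistic| ≥
  |observed|, the observed assignment counted in the numerator, so
  p ≥ 1/70 and the test is valid by construction; the minimum attainable
  two-sided p at 4/4 is 2/70 ≈ 0.0286. A Monte-Carlo mode (add-one
  estimator) covers designs past the enumeration cap.
- **BCa bootstrap**: groups resampled independently (stratified), default
  20,000 resamples; bias-correction z0 from the proportion of bootstrap
  statistics below the observed value (ties counted half, proportions
  clipped away from 0/1); acceleration from grouped delete-one jackknife
  influence values pooled across both groups. With z0 = a = 0 the interval
  reduces exactly to the percentile interval (asserted in tests). A
  degenerate bootstrap distribution returns a zero-width interval with a
  warning. Calibration is verified by simulation: ≈95% coverage of a true
  mean difference at n = 15/15 across 300 replicates of 2,000 resamples.

Reported effect sizes are rounded to 3 decimals in CLI/pipeline outputs;
library functions return full precision. No parametric t/Welch p-values are
produced, and no multiplicity correction is applied (a single prespecified
primary composite). Point estimates are reported with CIs and exact p's
descriptively; wide BCa intervals at n = 4/4 are expected and are not
converted into significance claims.

## Misbinding model

`P(M = veridical | S) = σ(α·P_S − β·G)`, σ the logistic function, P_S the
structural-plausibility score of the dreamed sequence and G the gating
integrity of the REM physiology it occurred in (operationally: an affine
map of the RGI composite; identity by default). There is no intercept: at
the origin of the standardized predictor scale the model is maximally
uncertain, and the P = 0.5 decision boundary is exactly the line
G = (α/β)·P_S. α and β are identified only relative to the predictor
scales (c·P_S with α/c is observationally identical); predictors should be
standardized before interpretation.

The sigmoid is evaluated branchwise (`1/(1+e^{−x})` for x ≥ 0,
`e^x/(1+e^x)` otherwise): stable over the full double range and exactly
0.5 at 0, so balanced inputs whose products α·P_S and β·G are equal as
floats return exactly 0.5.

Estimation is in-house IRLS on the exact log-likelihood (the estimator is
part of the package's test surface): convergence when the log-likelihood
changes by < 1e-10, max 100 iterations; standard errors from the inverse
observed information. Perfect separation is detected as (numerically) zero
residual deviance and raised as an error naming the condition, since the
MLE then diverges. The fit agrees with a direct Nelder-Mead optimization
of the likelihood to 6 decimals and recovers (α, β) = (1.5, 2.0) from
n = 2,000 simulated outcomes with RMSE < 0.15 over 100 replicates.

`plausibility_score` (mean of bounded structural sub-scores, then
z-standardization) is an explicit placeholder: no validated
operationalization of P_S exists, and fitting α, β to real dream-outcome
labels is out of scope.

## Pipeline

`run_pipeline` chains simulate → extract → RGI → stats → phase-space grid
per channel (C3-C4 primary, F3-F4 sensitivity), writing `features.csv`,
`rgi.csv`, `reference.json`, `stats.json` and `grid.csv`. Channels differ
only by seed stream: channel labels are metadata, not physiological models.
One global seed feeds per-stage children via
`numpy.random.SeedSequence(seed).spawn` in a fixed order (one child per
channel, then one for the bootstrap), all derived integer seeds kept below
2^31; identical config + seed reproduces every output byte-for-byte.

Cohort modes: `table` (default) draws feature tables directly — the mode
used for statistical calibration checks, where thousands of replicates are
needed; `signal` synthesizes a hypnogram and a 5-min coupled epoch per
subject (κ from the inverse Bessel ratio at the subject's target coupling)
and runs the full extraction stack, so the demo exercises every stage.
Problem sizes in the test suite (5-min epochs, 300-replicate coverage
simulations at 2,000 resamples, 100-replicate recovery runs) were chosen so
the whole suite completes in well under a minute of CPU while keeping every
Monte-Carlo check's sampling error several times smaller than its
tolerance.

## Known limitations

- The synthetic cohort is a stand-in, not a reconstruction of any real
  cohort; no generative model of the clinical data exists in public form.
- `RGI_min` and the distance's sign rule are package design decisions
  (see above), so absolute composite values are not comparable across
  implementations that choose differently; directions and g magnitudes on
  a fixed definition are.
- The spindle detector undercounts when burst occupancy approaches one per
  SO cycle (merged events), and the coupling estimate inherits phase noise
  from the SO filter at low SNR.
- θ and γ (the oscillatory organisation G summarises) are not modeled as
  separate quantities; G enters only as a scalar.
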