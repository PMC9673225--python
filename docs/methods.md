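# Methods

This note documents the models, numerical choices and limitations behind
`icpw`: the synthetic waveform/cohort generators, the pulse pipeline, the
morphology estimator, and the diagnostic-accuracy statistics.

## Pulse and session model

A single cardiac pulse is modeled as the sum of three Gaussian components on
normalized cycle time u ∈ [0, 1):

    y(u) = Σᵢ Aᵢ · exp(−(u − μᵢ)² / (2σᵢ²)),   i ∈ {P1, P2, P3}

Gaussians were chosen over gamma or raised-cosine kernels because they are
smooth, analytic, and need only two parameters per peak; no functional form
is physiologically canonical for cranial-deformation pulses.  The default
template places the percussion, tidal and dicrotic components at latencies
0.13 / 0.40 / 0.70 of the cycle with widths 0.07 / 0.12 / 0.16 and amplitudes
1.0 / 1.12 / 0.65 (arbitrary units), giving an achieved P2/P1 of 1.16, near
the cohort median of 1.15.  `shape_with_ratio` adjusts the tidal amplitude to
hit any target achieved ratio; worsening compliance is emulated purely
through that amplitude.

**Achieved versus component amplitudes.**  Overlapping components shift the
extrema of the summed curve, so ground truth is defined as the peak values of
the *sum* (read off a 10⁵-point grid inside the standard latency windows),
not the component amplitudes — that is what any peak detector, including this
package's, actually sees.  The generator's grid reader and the analysis-side
peak locator are deliberately separate code paths so tests can compare them
as independent routes.

A session concatenates beats of duration 60/HRᵢ seconds, where HRᵢ has
relative beat-to-beat jitter (default 2%, lognormal-free Gaussian
multiplier); each beat is the template evaluated on its own fractional time,
so heart-rate variation rescales but never distorts the shape.  The template
rises from its onset and is still decaying at the beat end, which makes the
true waveform minimum coincide with each beat boundary — the quantity the
onset detector estimates.  Additive terms: sinusoidal respiratory drift
(default 0.3 au at 0.25 Hz), white noise (default SD 0.05 au, about 4% of
peak amplitude), and motion artifacts as 0.3-s half-sine transients of 5×
the clean peak-to-trough amplitude at Poisson times (default 0.5/min) — the
simplest event model that exercises quality-control rejection.  The
co-recorded invasive ICP channel is the true mean ICP plus a mean-zero scaled
pulse train (3 mmHg peak-to-trough) plus 0.2 mmHg noise, so per-minute ICP
means are unbiased for the true mICP.  Defaults are 600 s at 72 bpm
(≥ 700 beats per session, matching the monitoring protocol) and 200 Hz; the
device sampling rate is not published, so 200 Hz is an assumption, exposed as
a parameter.  Every entry point takes a seed and uses one local
`numpy.random.Generator`; there is no global RNG state.

## Cohort model

Session mean ICP is log-normal — the cohort quartiles (median 14, Q1 11,
Q3 19 mmHg) are right-skewed — with (μ, σ) fitted by least squares to the
three quantile equations (closed form: σ from the log-IQR, μ the mean of the
three implied location estimates).  This fit gives σ_mICP ≈ 6.6 mmHg and an
implied IHT prevalence P(mICP > 20) ≈ 0.20.

Session P2/P1 follows the linear link `0.82 + 0.02·mICP + e`,
e ~ N(0, σ_e), truncated (clipped) to the physiologic band [0.4, 2.2].  By
default σ_e is derived from the correlation identity

    r = bσ / sqrt(b²σ² + σ_e²)   ⇒   σ_e = bσ · sqrt(1/r² − 1)

for the target correlation r = 0.49, giving σ_e ≈ 0.23.  Clipping affects
well under 1% of draws, so the realized correlation stays within 0.05 of the
untruncated target (verified at n = 10⁵).  Outcome groups (SB/MV/ED) and
covariates (age, sex, pathology, neurosurgery status) are drawn independently
with the observed cohort frequencies; they exist for table-building and
subgroup analyses, and no index depends on them.

**Two calibrations, deliberately separate.**  The linear-link cohort
reproduces the mICP–P2/P1 *correlation*; the binormal score model (below)
reproduces the *ROC operating points*.  A single homoscedastic linear link
cannot do both — calibrated to r = 0.49 it yields an IHT AUROC near 0.65,
well below the published-scale 0.88 — and the data needed to constrain a
joint (non-linear, heteroscedastic) link are not available.  Tests and
acceptance checks therefore address each calibration with its own generator.

## Binormal operating-point calibration

`calibrate_binormal` solves, for scores of hypertensive (pos) and normal
(neg) patients,

    P(X_pos > c) = sens,  P(X_neg ≤ c) = spec,
    Φ((μ_pos − μ_neg)/√(σ_pos² + σ_neg²)) = AUC

with σ_neg fixed (default 0.15, keeping negative-class ratios in a
physiologic band around the 1.2 cutoff) to make the 3-equation / 4-unknown
system determinate.  Substituting μ_neg = c − σ_neg·Φ⁻¹(spec) and
μ_pos = c + σ_pos·Φ⁻¹(sens) reduces the system to one equation in σ_pos,
solved by bracketed root finding to residual < 1e−8.  The reduced equation
can have **two roots**; the solver prefers a positive class at least as
heterogeneous as the negative one (σ_pos ≥ σ_neg — the physiologic case, as
hypertensive patients are the more variable group), tie-broken toward the
solution closest to σ_neg.  This makes a round trip on an equal-SD generating
pair exact while selecting σ_pos ≈ 0.66 (μ_pos ≈ 1.88, μ_neg ≈ 1.089) for the
default targets AUC 0.88, sens 0.85, spec 0.77 at c = 1.2.

## Pulse pipeline

1. **Band-pass** 0.5–15 Hz, 4th-order Butterworth applied forward-backward
   (zero phase), removing baseline wander below the cardiac band without
   shifting peaks.  Requires fs ≥ 30 Hz.
2. **Onset detection.**  The beat period is estimated from the signal
   autocorrelation in the 0.33–2 s lag band; because the autocorrelation also
   peaks at period multiples, the estimator takes the earliest local maximum
   within 75% of the band maximum rather than the global argmax (which can
   lock onto a harmonic).  One anchor per beat is placed at the systolic
   max-upslope point (dominant first-derivative peak, refractory 0.6×period);
   the onset is refined backward to the curvature maximum — the corner of the
   onset trough.  The corner is used instead of the trough minimum because
   zero-phase smoothing at 15 Hz shifts the minimum of an asymmetric trough
   by ~20 ms while leaving the corner nearly in place; on noiseless
   simulations recovered onsets sit within 5 ms (one sample) of truth.  A
   first beat whose refinement window is clipped by the recording start walks
   back along the upstroke and clamps at sample 0.
3. **Segmentation** is trough-to-trough (onset-to-onset, half-open
   [onset, end)), the onset trough being the natural amplitude baseline; the
   trailing partial beat is dropped and each beat is assigned to the minute
   containing its onset.
4. **Quality control.**  Each beat is resampled to a fixed 100-point
   normalized base (latency quantization 1% of cycle) and compared with the
   pointwise-median beat of its minute: accepted iff Pearson correlation
   ≥ 0.8 and peak-to-trough amplitude within [0.3×, 3×] the minute's median.
   A single-beat minute accepts by convention.  Accepted + rejected counts
   are reported per minute.
5. **Averaging.**  The minute pulse is the pointwise mean of accepted beats;
   a minute with fewer than 30 accepted beats is flagged invalid and excluded
   from session aggregation (mirroring exclusion of poor-quality recordings),
   not raised as an error.

All steps are scale-free, so the pipeline is invariant to gain and offset of
the arbitrary-unit sensor signal; this is verified end-to-end in the tests.
The QC thresholds are defaults in `AnalysisConfig`, not published values.

## Morphology

On the 100-point averaged pulse, amplitudes are measured above the
onset-trough baseline (the first sample).  P1 is the highest local maximum
with latency in [0.05, 0.28] of the cycle, P2 in (0.28, 0.60], P3 in
(0.60, 0.90] (reported but feeding no index).  The windows reflect the
physiological ordering of percussion and tidal waves; no published window
values exist, so they are configurable.  When a window holds no local maximum
(peaks merged into a shoulder), the fallback takes the zero-crossing of the
second derivative after 5-point smoothing — the simplest rule resolving the
common "P1 rides on the P2 upstroke" morphology; if that also fails, the
window maximum is used and the result flagged low-confidence.  Ties between
equal maxima resolve to the earlier peak.  The session statistic is the mean
of per-minute ratios (median available via config; the aggregation statistic
is not published).  A zero P1 amplitude raises an undefined-ratio error
rather than returning infinity.

## Diagnostic statistics

* AUROC is tie-aware Mann–Whitney concordance computed via midranks.
* DeLong placement values give the AUROC variance, normal-approximation CIs
  (clipped to [0, 1]; a zero-variance AUC of 0 or 1 collapses the CI to a
  point and is flagged) and the paired two-classifier z-test.
* Operating points use the strict `score > cutoff` convention throughout,
  matching how the clinical cutoffs are printed; boundary scores classify
  negative.  Sensitivity/specificity carry Wilson 95% intervals (better
  small-sample behavior than Clopper–Pearson; the interval method behind the
  published values is unstated).
* Categorical tables: Pearson chi-square **without** continuity correction
  when all expected counts are ≥ 5, otherwise Fisher's exact — exhaustive
  enumeration when the margin-bound table count is ≤ 2·10⁵ (always the case
  for 2×2 and small 3×2), otherwise a margin-conditional Monte-Carlo
  estimate (Patefield sampling, 20 000 tables, fixed internal seed, (k+1)/(B+1)
  correction), the same approach as R's `fisher.test(simulate.p.value=)`.
  The `force` argument overrides the dispatch; note that the reconstructed
  hypertension-by-outcome table has expected counts below 5, so its published
  chi-square p = 0.013 is reproduced under `force="chi2"` while the automatic
  dispatch chooses Fisher (p = 0.0152).
* Continuous comparisons dispatch on a per-group Shapiro–Wilk screen at
  α = 0.05: ANOVA with Tukey HSD post hoc when all groups pass, otherwise
  Kruskal–Wallis with Dunn–Bonferroni (tie-corrected).  Callers can force
  either family.  All-identical data short-circuit to p = 1.
* AUC sample size uses the Hanley–McNeil exponential-approximation variance:
  the smallest total n (at the given negative:positive ratio) such that a
  two-sided α-level test of H₀: AUC = AUC₀, with null-variance rejection
  region, reaches the target power under the alternative variance.  For
  AUC 0.85 vs 0.6 at 80% power and ratio 1 this yields 17+17 = 34; a seeded
  Monte-Carlo of the same test under an equal-SD binormal alternative
  confirms power ≈ 0.82 at that n and < 0.8 at n−2.  Published sample-size
  figures for this design depend on unstated allocation-ratio and α
  assumptions and are not used as truth.

## Problem sizes and determinism

The test suite simulates 10-minute sessions at 200 Hz (≈ 720 beats each); the
pipeline-recovery property uses 200 seeded replicates at default noise,
calibration-closure checks use 10⁵ draws, bootstrap/coverage/type-I checks
use 200–2000 seeded replicates, and the power simulation 10⁴–2·10⁴
replicates.  Every stochastic test and script fixes its seeds, so reruns are
bit-identical.

## Limitations

* The generator emulates beat-to-beat timing jitter, drift, noise and
  transient artifacts, but not sensor-specific mechanics (contact-pressure
  changes, slow detachment drifts), arrhythmia, ABP synchronization, or
  pathology-specific waveform families; passing recovery tests demonstrates
  estimator correctness under the stated model, not device-level validity on
  real patients.
* Morphology works on minute-averaged pulses only; beat-by-beat analysis and
  P2/P1 time-series alarms are out of scope.
* The published morphology algorithm is built on ABP-synchronized beat
  detection; no ABP-synchronized variant is reconstructable from public
  information, so onset detection here is single-channel by design.
* The linear cohort link is a correlation-calibration device, not a
  physiological model; see "Two calibrations" above.
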