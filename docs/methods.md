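# Methods

This note documents the models, conventions and numerical choices behind
`chronoerp`: a pipeline from continuous multichannel EEG to quantified
event-related potentials (ERPs) in a 1200-ms time-production task, together
with a synthetic-cohort generator that provides a recoverable ground truth.

## The task and its behavioral model

Subjects see a visual cue and press a key when they estimate 1200 ms have
elapsed; 300 trials per subject, inter-trial interval uniform on 800–2200 ms.
Responses are classified by reaction time (RT, ms after cue onset):

| category | RT window |
|---|---|
| early    | [400, 1000) |
| correct  | [1000, 1400] |
| late     | (1400, 2000] |
| miss     | < 400, > 2000, or no press within 3000 ms |

The shared endpoints are resolved half-open (1000 and 1400 belong to
*correct*) so every RT maps to exactly one category.

RTs are modeled per group as a shifted lognormal, `RT = shift + exp(N(µ, σ))`,
plus an explicit no-response probability.  `calibrate_rt_model` solves for
`(shift, µ, σ, p_no_response)` by deterministic least squares so the analytic
category probabilities hit the target rates within 0.005 absolute per
category (group defaults: controls 64/17/18/1 %, ADD 44/30/23/3 %, ADHD-C
49/30/18/3 %).  The family is right-skewed with positive support, so target
vectors demanding exactly zero mass outside [400, 2000] are unreachable; the
calibrator then raises an explicit failure rather than returning a poor fit.
Degenerate all-correct targets resolve to a near-delta distribution inside
the correct window.

## Preprocessing

* **Band-pass 0.5–20 Hz, 48 dB/oct realized slope, zero phase.**  The filter
  is the order-8 Butterworth band-pass applied forward and backward.  It is
  realized in the frequency domain: the recording's spectrum is multiplied by
  the squared magnitude response of the digital (bilinear-prewarped) design,
  which is the steady-state response of `sosfiltfilt` with the same design
  (interior agreement ~1e-5 relative; the FFT path is several times faster on
  ~20-minute records and introduces no group delay).  Records are zero-padded
  by 4 s before the FFT so the acausal response tail cannot wrap around.
* **Resampling 500 → 256 Hz** by polyphase anti-aliased resampling; event
  onsets are remapped to the nearest sample.
* **Artifact rejection** on epoched µV data, any channel rejecting the whole
  trial: (a) amplitude beyond ±200 µV; (b) peak-to-peak range above 200 µV in
  any sliding 200-ms window; (c) peak-to-peak range below 0.5 µV in any
  sliding 100-ms window.  Windows advance one sample at a time
  (`round(window_ms · rate / 1000)` samples long).  Rejection runs separately
  per segmentation scheme, before any spatial transform, and is logged per
  trial with the first violated criterion and channel.

Processing order is fixed: filter → resample → segment → baseline → reject →
spatial transform (CSD).

## Segmentation and baselines

* **Stimulus-locked**: [−2000, +3000] ms around cue onset, baseline mean of
  [−200, 0] ms pre-cue subtracted per channel and trial (P1/N1 analysis).
* **Response-relocked (CNV)**: each baseline-corrected stimulus epoch is
  re-windowed to [−2000, +1000] ms around that trial's response with *no*
  re-baselining, so slow preparatory activity is measured against the fixed
  pre-cue level.  Values are the identical samples of the stimulus epoch
  (tested as an exact identity).  Misses are excluded.
* **Feedback-locked (FRN)**: [−200, +1500] ms around the response, cut from
  the continuous filtered record and baseline-corrected to [−200, 0] ms
  pre-response.  Early and late trials are pooled as the "error" condition.

Analysis windows `[a, b]` are closed; the boundary samples are
`ms_to_samples(a)` and `ms_to_samples(b)` (round half away from zero).

## Current source density

Scalp potentials are converted to reference-free current source density with
the spherical-spline surface Laplacian: spline order m = 4, ridge
λ = 1e-5 on the diagonal of G, 50 Legendre terms, head radius 8.75 cm; the
operator output is scaled by 1/radius² to µV/m².  The constant term is
carried explicitly, so the operator annihilates any added constant (rows sum
to ~0).  The implementation is verified against (i) a brute-force KKT
least-squares spline solve on small montages (< 1e-6 relative) and (ii) the
MNE implementation with matched parameters (~1e-10 relative).

Because no electrode coordinate table is available for the 60-channel
equidistant cap, `make_equidistant_montage` generates a deterministic
golden-angle spiral on the upper unit sphere (z > −0.2) and assigns Cz, FCz
and P7/P8/P9/P10 to the geometrically appropriate sites.  This layout is a
stand-in, adequate for CSD geometry but not anatomically registered.

An **identity spatial mode** replaces the CSD operator with the identity
(units tagged "µV/m² (nominal)").  It exists so that generative component
amplitudes — specified directly in the measurement space — can be recovered
without spatial mixing; all parameter-recovery results use this mode.

## Component quantification

* **P1 / N1**: windowed mean over P7/P8/P9/P10 of the condition-average
  waveform; windows keyed to group (P1 controls 115–140 ms, patients
  125–150 ms; N1 controls 185–205 ms, patients 195–215 ms).
* **CNV**: mean amplitude at Cz in four pre-response windows (w1 −825…−775,
  w2 −625…−525, w3 −225…−175, w4 −50…0 ms), per accuracy condition.
* **FRN**: at FCz, the minimum of the condition-average waveform within each
  of two 10-ms peak windows (controls & ADD 200–210 and 300–310 ms; ADHD-C
  225–235 and 320–330 ms); peak-to-peak = value at peak 2 − value at peak 1;
  the FRN effect is p2p(correct) − p2p(error).  Peak-to-peak is invariant to
  any offset added to a condition waveform.  An alternative reading of
  "peak-to-peak" (each negativity against its preceding positivity) exists;
  the two-negative-peaks difference is implemented.
* "Mean peak amplitude" is implemented as the windowed mean of the
  trial-average waveform: the windows are narrow and a per-trial extremum
  would be noise-biased.
* **Electrode validation**: for a given window, each electrode's per-subject
  mean is compared against the per-subject mean of all other electrodes with
  a paired two-tailed t-test; an electrode is selected iff p < 0.0007 (the
  published Bonferroni-corrected threshold, used verbatim even though
  0.05/60 ≈ 0.00083) and its amplitude is larger in the expected polarity.

## Statistics

`mixed_anova` is a balanced split-plot sums-of-squares decomposition for one
between-subjects factor and one or two within-subjects factors (arbitrary
group sizes, complete within-cells; incomplete subjects are excluded listwise
with a logged count, duplicate or missing cells raise).  Each within effect
is tested against its own subject-interaction error stratum.  A
Greenhouse–Geisser epsilon is computed per within effect from the pooled
within-group covariance of the subject cell scores,
ε = (tr CSC′)² / (d · tr (CSC′)²) with orthonormal contrasts C, and the
GG-corrected p is always reported next to the uncorrected one — no silent
switching.  Effect sizes are partial eta squared,
ηp² = SS_effect/(SS_effect+SS_error) = F·df1/(F·df1+df2).  Follow-ups are
paired/independent t-tests with Bonferroni adjustment min(1, m·p); zero
-variance comparisons are flagged degenerate.  Correlations are Pearson
product-moment with the two-tailed t-transform p.  All tests are two-tailed
at α = 0.05.

## The synthetic generator

Each subject is a continuous 500-Hz recording (60 channels by default) built
from:

* **Background noise** per channel: 1/f (default exponent 1, 10 µV rms) +
  alpha-band (Gaussian bump at 10 Hz, 4 µV rms) + white (3 µV rms), drawn in
  a single spectral pass with analytic scaling.
* **P1/N1** Hann lobes on the four parietal channels (±12 µV, stimulus-locked,
  group-specific latencies).
* **CNV** at Cz: a piecewise-linear pre-response ramp, flat at a plateau
  value across each analysis window, linearly interpolated between windows,
  ramping from zero at cue onset and decaying to zero 300 ms after the
  response.
* **Feedback complex** at FCz: two negative Hann deflections (80 ms wide)
  centered on the group's peak windows, with condition-specific depths.
* **Artifacts** (per-trial rates): blinks — frontal-weighted positive
  transients of 100–400 µV tripping the amplitude criterion; "drift" —
  a high-amplitude ~3-Hz slow wave (±120–160 µV, swing > 200 µV within
  200 ms while staying inside ±200 µV) tripping the max-difference
  criterion (a literal sub-0.5-Hz ramp would be removed by the high-pass and
  trip nothing); flatlines — 800-ms zeroed segments on one channel tripping
  the low-activity criterion.  Default rates 6 / 3 / 1.5 % per trial put the
  realized per-subject rejection around 8–12 %, inside the plausible 3–20 %
  band.

**Measurement-space calibration.**  Component targets (CNV window amplitudes;
FRN peak-to-peak values) are defined as what the *pipeline measures* in
identity spatial mode, not as raw injected amplitudes: the 0.5-Hz zero-phase
high-pass materially attenuates and distorts second-scale ramps, so injecting
the printed values verbatim would not recover them.  Once per group the
generator simulates a noise-free single-channel event sequence (800 trials,
fixed internal seed, independent of the user seed), measures the pipeline
response to unit basis injections (four CNV plateau bases; two FRN deflection
bases), and solves the resulting small linear systems so the expected
measured values equal the targets.  The residual is the sampling error of the
calibration sequence (RT/ITI jitter of the inter-trial filter bleed),
empirically < 0.5 µV/m² for a single noise-free subject and negligible at
cohort scale.  Because the measurement operator is linear, additive noise
leaves recovery unbiased.

Per-condition FRN peak-to-peak targets are the published difference applied
to a common error-condition value of −10 µV/m² (only the difference is
published).  The ADD CNV window-3 target is 0.0 µV/m², derived from the
published pooled value for windows 2 and 3.

**Symptom scores.**  Inattention/hyperactivity/impulsivity are clipped
Gaussians with the published group moments.  Inattention is coupled to the
realized per-subject correct count through a Gaussian copula: the normal
scores of the correct counts enter the inattention latent with correlation
ρ = −0.54 for the ADD group (0 elsewhere); Monte-Carlo checks show the
realized Pearson r is unbiased for the target with sd ≈ 0.05 at n = 200.

**Determinism.**  Per-subject seeds fan out from the master seed by a
counter-based seed-sequence over (master, group, index); identical seeds give
bit-identical recordings.

## What the synthetic data does and does not emulate

The generator reproduces the study's *measured surface*: category rates, CNV
window amplitudes, FRN differences, P1/N1 deflections, symptom moments and
the inattention–performance coupling, under realistic noise and artifact
rates.  It does not model volume conduction (components live on single named
channels; spatial mixing enters only through the optional CSD), trial-order
learning, latency jitter of the components, eye-tracker channels, or
realistic blink topographies.  Passing recovery tests therefore demonstrates
that the pipeline is an unbiased measurement chain for signals of this form —
not that it would reproduce any particular clinical dataset.

## Problem sizes and tolerances

Parameter-recovery runs use 16 subjects × 300 trials per cohort averaged
over 10 seeds, with a 16-channel montage: in identity spatial mode the
recovered quantities live on single named channels (Cz, FCz) and are
independent of montage size, while the smaller cap keeps a full
ten-seed, three-group recovery under ~15 minutes on one CPU.  Behavioral and
correlation analyses use the EEG-free fast path (trial plans only).
Noise-free single-subject recovery is asserted within 0.5 µV/m²
(calibration-sequence residual); cohort CNV means within ±1.5 µV/m² and FRN
differences within ±2 µV/m² of target; behavioral rates within ±3 percentage
points; the coupling correlation within ±0.1.

## Known limitations

* The montage is a generated stand-in, not the (unpublished) recording cap.
* The mixed ANOVA requires complete within-cells; there is no likelihood
  -based treatment of missing data.
* EDF export quantizes to 16 bits over ±1000 µV (~0.03 µV steps); artifacts
  above 1000 µV would clip (none are generated above ~560 µV).
* Source localization and ICA-based artifact removal are out of scope.
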