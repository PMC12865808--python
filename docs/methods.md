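# Methods

This note documents the models and procedures implemented in `dyadsync`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for reproducing
results.

## Study structure being emulated

The package targets dyadic fNIRS hyperscanning designs of the following
shape: pairs of participants are assigned to a 2 × 2 between-dyad design
(Laughter yes/no × Social context yes/no), recorded at 7.81 Hz over 16
channels per participant (four channels over each of four regions of
interest: left/right inferior frontal gyrus, left/right temporoparietal
junction) during a ~10-min manipulation phase and a ~10-min free interaction.
Laughter is annotated as onset/offset intervals per participant; liking,
bonding (IOS) and prosociality questionnaires are collected afterwards.
Interbrain synchrony is the band- and COI-restricted average of wavelet
transform coherence per ROI pair, phase, and 5-min interval; it is the
dependent variable of the condition models and the mediator of the
laughter → synchrony → outcome mediation.

## Synthetic-data generator

Each channel of a dyad's recording is

    x = κ·c_shared + sqrt(1 − κ²)·c_indep + background + physiology + noise

where `c_shared` (per dyad × phase) and `c_indep` (per participant × ROI) are
unit-SD Gaussian noise hard-band-passed to the coupling period band
(default 8–75 s); `background` is 1/f noise (slope 1, amplitude 0.5);
`physiology` is the standard fNIRS nuisance taxonomy — cardiac ~1.0 Hz
(amplitude 0.3), respiratory ~0.25 Hz (0.2), Mayer waves ~0.1 Hz (0.15),
all with small per-participant frequency jitter and random phases — and
`noise` is white channel noise (SD 0.3). Channels within an ROI share the
ROI latent component, so ROI-averaged signals retain the coupling while
channel noise averages down.

Two consequences worth knowing:

* With this mixing, the cross-brain correlation of the in-band components is
  κ², so the **squared** coherence grows like κ⁴: κ = 0.3 is essentially
  indistinguishable from zero at realistic cohort sizes, while κ = 0.6 and
  0.9 are clearly resolvable. Recovery checks therefore test a one-sided
  positive trend over κ ∈ {0, 0.3, 0.6, 0.9} rather than strict ordering of
  neighbouring sample means.
* Smoothed wavelet coherence of independent signals has a positive bias
  (~0.43 for 5-min segments, band 8–75 s, with the defaults below). This is
  inherent to coherence estimation and is the reason the pseudo-dyad
  surrogate null is part of the chain.

Motion spikes are available (`motion_rate_per_min`) but default to 0: the
baseline cohort is clean so the quality gate passes by construction, and the
motion operators are exercised by injecting artifacts explicitly.

Laughter bouts are a homogeneous Poisson process of onsets with log-normal
durations (mean 3 s, σ_log 0.6), merged within a track. Rates are derived
analytically per condition and phase from published per-cell dyad-union
means (manipulation: 135.0 / 51.2 / 36.1 / 0.52 s; free interaction:
51.2 / 47.6 / 50.2 / 50.4 s): with onset rate λ and mean duration μ a
participant laughs a fraction p = 1 − exp(−λμ) of the time (M/G/∞ busy
fraction), two independent participants jointly q = 1 − (1 − p)², and λ is
chosen so q·window matches the target mean. Windows include the pre-onset
extension (defaults: 282 s before the manipulation task, 60 s before the
free interaction — the published window means).

Outcomes follow the linear structural model M = a·T + ε₁,
Y = intercept + c′·T + b·M + ε₂, clipped to each instrument's scale (liking
0–8, IOS 1–7, prosociality ratios 0–1). The default paths are null
(a = b = c′ = 0): the baseline cohort carries no planted mediation, matching
the emulated study's headline result; recovery tests pass explicit non-zero
paths. Per-participant questionnaire items are derived from the dyad-level
outcome plus item noise so that composites and Cronbach's alpha behave
realistically.

What the generator does **not** emulate: hemodynamic response convolution
with task events, optode–scalp coupling physics, facial/vocal behavior, or
any nonstationarity of coupling within a phase. Passing tests therefore show
that the chain recovers planted coupling and planted structural paths under
Gaussian band-limited signals — not that it would detect any particular
real-world effect size.

Reproducibility: one master seed; per-dyad and per-purpose substreams are
spawned as `SeedSequence([master_seed, dyad_index, stream_code])`, so
generation order does not matter.

## Preprocessing

Fixed order: intensity → OD → motion detection → spline correction → wavelet
despiking → band-pass → MBLL. No step changes length or sampling rate.

* OD(t) = −log10(I(t)/mean(I)) per channel and wavelength.
* Motion: a sample is flagged when the moving-window (1 s) peak-to-peak
  change exceeds 13.5 × the channel's sample-to-sample SD or 0.4 in absolute
  OD; flags are dilated to whole windows.
* Spline correction: within each flagged segment the smoothing-spline trend
  (p = 0.99, csaps-style λ = (1−p)/p) is subtracted anchored at the left
  edge and the removed offset is propagated to the tail, so baseline jumps
  are removed without boundary discontinuities. Fully-flagged channels are
  marked bad and passed through.
* Wavelet despiking: db2 decomposition (periodised); detail coefficients
  farther than 1.5 IQR from their level's median are zeroed. An infinite
  factor is an exact identity (reconstruction error < 1e−10).
* Band-pass: zero-phase 3rd-order Butterworth, default 0.01–0.5 Hz.
* MBLL: per-sample 2×2 solve with shipped 760/850 nm extinction defaults,
  DPF 6.0/6.0, 3 cm separation — all overridable. Forward/inverse round-trip
  is exact to 1e−10.
* Quality: a channel is bad when its intensity CV exceeds 0.15 or it is
  flat; an ROI is bad when all four channels are bad; a dyad is excluded for
  an ROI pair when any involved ROI of either member is bad.

The motion/filter thresholds are package choices (the reference
preprocessing lived in a closed toolchain); every threshold is exposed in
`PreprocessParams`.

## Wavelet transform coherence

Analytic Morlet with ω₀ = 6 (Fourier period = 4πs/(ω₀ + √(2+ω₀²))), computed
in the frequency domain with zero padding generous enough that wraparound is
below 1e−6 at the largest scale; this equals the direct convolution with the
sampled wavelet, and the test suite holds the implementation to a
direct-convolution oracle at 1e−6. The scale grid uses 12 voices per octave.

Smoothing: per scale, a Gaussian in time with SD s/√2 (in seconds; config
`time_smooth_sd_scales`), then a 0.6-octave boxcar across scales. Coherence
is clipped to [0,1] (the same smoothing in numerator and denominator bounds
it by Cauchy–Schwarz up to numerics). The cone of influence uses the Morlet
e-folding time √2·s; cells inside the COI are removed (not zero-filled)
before averaging. The analysis band per segment is 8 s to duration/4
(a 300 s segment gives 8–75 s ≈ 0.0133–0.125 Hz); segments shorter than
4 × 8 s raise a segment-too-short error.

ROI signals are the mean of good channels (channels-first; a channel-pairs
alternative is available via `channels_first=False` — the aggregation order
is not dictated by the emulated analysis, channels-first is the default
because it matches one-value-per-ROI-pair reporting). Heterologous pairs
average the two cross-assignments since dyad members are exchangeable. Each
phase is split into two equal intervals, COI-masked independently.

## Pseudo-dyad surrogates

Each participant is paired with `n_surrogates` (default 100) randomly chosen
non-partners from the phase's pool (condition- and gender-unrestricted;
restrictable by flags), with replacement only when the pool is smaller than
requested (logged). Coherence matrices are averaged elementwise on the
common grid before the band/COI reduction (matrix-then-scalar; on a common
grid this equals scalar-then-mean by linearity, which is asserted in tests).
Unequal lengths are truncated to the shorter series.

The real-vs-surrogate comparison fits each group's mean with its own
residual SD (two intercept-only Gaussian models) and reports the paired
difference posterior. A pooled-variance group model was measured to be
anticonservative here — pseudo-dyad values are averages over many pairings
and have roughly half the SD of real-dyad values, so pooling understates
the SE of the difference (difference-ETI coverage ~85% instead of 95% on
uncoupled cohorts); the group-specific-variance comparison restores nominal
coverage.

## Bayesian models

Gaussian likelihoods throughout: y = Xβ + u_dyad + ε, u ~ N(0, τ²),
ε ~ N(0, σ²). The formula grammar `y ~ A*B*C + x + (1|dyad)` expands `*` to
the full factorial set; two-level factors are effect-coded ±0.5 so main
effects are means of simple effects. Priors: coefficients N(0, 5·sd(y)) and
half-normal(5·sd(y)) scales by default ("noninformative" on the response
scale); the intercept prior defaults to N(mean(y), 5·sd(y)) and is meant to
be supplied explicitly where prior knowledge exists — the shipped pipeline
config uses N(0.3, 0.2) for synchrony responses, a typical band-averaged
coherence level.

Sampling is an in-package MCMC: conjugate multivariate-normal Gibbs updates
for β and the random intercepts, stepping-out slice sampling on log σ and
log τ (half-normal priors). Default 4 chains; convergence is gated on
rank-normalised split R-hat ≤ 1.01 and bulk ESS ≥ 400 (Geyer initial
monotone sequence estimator); both are cross-checked against an independent
implementation in the test suite. Prior and posterior predictive checks
report the observed-mean percentile among replicated means.

Bayes factors: for nested comparisons, a Rao-Blackwellised Savage–Dickey
ratio — the conditional posterior of the dropped coefficient block given
each draw of the remaining parameters is Gaussian in closed form, so the
posterior density at zero is an average of exact conditional densities
(MC error from 16 batch means). Non-nested comparisons use bridge sampling
of the marginal likelihood with the random intercepts integrated out
analytically per group and a moment-matched Gaussian proposal in the
unconstrained space. BF(model, itself) ≡ 1; reciprocity holds within MC
error. The sequential design monitor accrues dyads in stream order, starts
once every cell holds 20 dyads, computes BF10 at each step, and stops at
BF > 5 (support-full) or BF < 0.20 (support-null), else reports
resources-exhausted with the full trajectory.

## Mediation

Two equations, M = α₀ + a·T + γ′C + ε₁ and Y = β₀ + c′·T + b·M + δ′C + ε₂,
fitted by the same sampler; their parameter blocks are independent a priori
and a posteriori, so index-paired draws are joint draws. Per draw
ACME = a·b, ADE = c′, total = c′ + a·b (exact identity in this linear,
no-interaction model), proportion mediated = ACME/total with draws at
|total| < 1e−8 excluded and the exclusion fraction reported (the ratio is
unstable near zero totals). Intervals are 95% equal-tailed quantiles with
linear interpolation. Social context enters both equations as a covariate
when the treatment is a laughter variable. The mediation grid runs one model
per treatment × mediator × outcome cell, flags cells whose ACME/ADE/b-path
ETI excludes zero, reports uncorrected intervals, and records per-cell
failures without aborting.

## Problem sizes used in checks

Simulation-based checks run at sizes chosen to make each property resolvable
while keeping a full run on one CPU comfortable: coupling-recovery cohorts
use 20 dyads per κ with one 5-min phase and one homologous ROI pair;
uncoupled real-vs-pseudo checks use 20 cohorts × 20 dyads with 5 surrogate
partners per participant; hierarchical recovery uses 20 replicates of 200
dyads; Bayes-factor calibration 20 replicates at n = 100; mediation recovery
n = 500 with a 10-replicate planted grid; generator calibration 1000 bout
replicates. The acceptance script uses 12-dyad cohorts for the coupling
curve and surrogate comparison. Coverage-style criteria are asserted at
≥ 90% (or ≥ 80% where the underlying event combines detection with
multiplicity) rather than at nominal rates, reflecting the reduced
replicate counts.

## Known limitations

* Gaussian likelihoods only; Likert outcomes are treated as continuous.
* No phase-lag/directed coupling, no time-resolved event-locked synchrony.
* The preprocessing operators are simplified, parameter-exposed stand-ins
  for a closed-source reference chain; they reproduce its intent
  (artifact suppression before band-passing and MBLL), not its exact output.
* Bridge-sampling MC error is a split-half estimate, adequate for the BF
  magnitudes compared here but not a substitute for repeated runs when BFs
  are near decision thresholds.
* The proportion-mediated summary is undefined when the total effect is
  near zero; the exclusion fraction should be inspected before interpreting
  it.
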