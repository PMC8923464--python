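# Methods

## Model overview

`anpitch` links parametric acoustic stimuli to predicted psychophysical
thresholds in three stages.

1. **Stimulus synthesis** (`anpitch.stimuli`).  All stimuli are calibrated
   pressure waveforms (Pa; a tone at L dB SPL has RMS 20 µPa·10^(L/20)).
   Pure tones and harmonic complex tones are 100 ms with 10-ms
   raised-cosine ramps.  The filtered-HCT variant synthesizes all
   harmonics up to Nyquist and applies a zero-phase 12th-order Butterworth
   bandpass with cutoffs at 5.5 and 10.5 × the nominal F0 (forward plus
   backward pass of the 12-pole design, i.e. the squared magnitude
   response); harmonics attenuated by more than 100 dB are omitted as
   numerically indistinguishable from absent.  Threshold-equalizing noise
   (TEN) is white Gaussian noise shaped by 1/√ERB(f) — its defining
   property, equal power through any ERB-wide auditory filter — and scaled
   so the power in the ERB at 1 kHz (132.6 Hz with
   ERB(f) = 24.7(4.37 f_kHz + 1)) matches the nominal level.  Component
   level roving is uniform ±3 dB and phase randomization uniform over
   360°, drawn from caller-supplied seeded generators only.  GEOM maskers
   sit at the geometric mean of the reference and target F0s with a
   broader 4–12 × F0 passband (or harmonics extended by one on each side
   in the discrete variant); DBL maskers flank the target F0 at −5.5 and
   +6 semitones (2^(ST/12)).

2. **Auditory-nerve front end** (`anpitch.frontend`).  Each CF channel is
   an analytic chain:
   - a 4th-order gammatone filter (cascade of complex one-pole sections,
     unity gain at CF) whose equivalent rectangular bandwidth follows the
     Glasberg–Moore human ERB, so Q_ERB rises from ≈ 8.4 at 2 kHz toward
     ≈ 9.2 at 20 kHz.  A Shera-style power law Q_ERB = q0 (CF/1 kHz)^q_exp
     is available in config; Glasberg–Moore is the default because the
     analytic-chain model family this front end reproduces uses human ERB
     filters, and the flatness of rate-place F0DLs across F0 follows
     directly from near-constant relative tuning.
   - half-wave-rectifying saturating transduction u/(1+u) with
     u = max(p, 0)/p_sat and p_sat = 0.05 Pa.  In the small-signal regime
     the drive is a half-wave-rectified sinusoid, which fixes the
     vector-strength ceiling at π/4.
   - a phase-locking lowpass: 7 identical first-order stages, with the
     per-stage cutoff derived so the cascade's composite −3 dB point is
     `pl_cutoff` = 2.5 kHz.  This calibration makes on-CF vector strength
     to 30-dB tones ≈ 0.41 at 1 kHz, ≈ 0.36 at 2 kHz, declining through
     2–6 kHz and below 0.1 above ~6 kHz — the rolloff regime in which
     phase locking is believed to become useless in the high-frequency
     range.  Only the composite cutoff is exposed; the figures above are
     properties of the default configuration, not separate parameters.
   - an affine map to rate, r = spont + clip(g·v, 0, max_rate − spont),
     with g = 16 000 spikes/s per unit drive and max_rate = 300 spikes/s.
     Together with p_sat this places the high-spontaneous-rate (HSR)
     rate-level threshold (criterion: mean rate 5% above spont) near
     0–2 dB SPL and the saturation knee near 35–40 dB SPL, so HSR fibers
     are saturated at 50 dB SPL while low-spontaneous-rate (LSR) fibers
     (25 dB less sensitive, spont 1 s⁻¹) remain unsaturated and preserve
     resolved-harmonic contrast in their excitation patterns.  Fiber-class
     defaults: HSR spont 60 s⁻¹ / 0 dB gain, MSR 18 s⁻¹ / −12 dB,
     LSR 1 s⁻¹ / −25 dB.

   The output is the *expected* (noise-free) instantaneous rate; Poisson
   variability enters only through the observer mathematics and the
   Monte-Carlo oracle.  Rate-level thresholds are calibrated per the
   standard protocol (25 log-spaced frequencies 0.2–20 kHz × 25 levels
   −10–40 dB SPL, linear interpolation of the rate-level function) and all
   simulation levels are stated re: these thresholds, which decouples
   threshold placement from the frequency axis.  A registry validates
   plug-in front ends with a probe stimulus (shape, finiteness,
   nonnegativity) so published nerve models can be substituted.

3. **Ideal observer** (`anpitch.observer`).  Fisher information for the
   Poisson population is computed by central finite differences of the
   rate map and trapezoidal time integration, with the fibers-per-CF
   multiplier applied per channel.  Roved parameters are sampled from
   their uniform synthesis distributions when averaging I(θ) (default 8
   draws, 4 in the desk preset), while the prior information matrix uses
   the normal approximations ν = 6 dB for the ±3 dB level rove and
   ν = 360° for the uniform phase rove — the same asymmetry keeps the
   information well defined for the uniform rove.  The rate-place observer
   is the same machinery applied after time-averaging each fiber's rate,
   which is equivalent to Poisson-count information T·(dr̄/dθ)²/r̄ per
   fiber.  JND = √variance-bound, reported in Hz and as % of baseline.

## Simulation protocols

FDL runs use 40 CFs log-spaced over 0.5–1.5 × f with 72 fibers per CF
(≈ 2880 ≈ 3000 HSR fibers near the tone, i.e. 60% of a 30 000-fiber nerve
scaled to the simulated octave); F0DL runs use 40 CFs over 5–11 × F0 with
51 fibers per CF.  F0DL stimuli are the filtered HCTs (sine phase unless
phase-randomized, no background noise), with the bandpass anchored to the
*nominal* F0 — reference and target share one filter, as in the behavioral
paradigm the simulations model — and per-component level set re: the
rate-level threshold at the 8th harmonic.  When roving, one level or phase
nuisance parameter is assigned to each component within 40 dB of the
passband maximum (harmonics 6–10 for the default cutoffs).  Threshold
curves are LOESS-smoothed (local linear, span 0.5) on log-log coordinates
and high/low anchors are read off the smoothed fit; the span is guarded by
a power-law recovery test.  The desk preset uses 9 log-spaced
frequencies/F0s (1.4–14 kHz; 0.18–1.8 kHz) at 30 dB re: threshold with 4
rove draws; the full preset uses 24 points at 20/30/40 dB with 8 draws.
Threshold ratios are computed on the relative (Δf/f) scale by default;
pure-tone FDL ratios are additionally reported on the Hz scale, the scale
on which FDL-versus-frequency curves are conventionally plotted.

## Numerical choices

- **Simulation rate.**  Discrimination runs use 500 kHz; everything else
  (calibration, population views) uses 100 kHz.  The half-wave rectifier
  generates harmonics of the stimulus without bound, and at 100 kHz the
  low-order folds across Nyquist (e.g. the 12th harmonic of an 8.5-kHz
  tone folding to 2 kHz) land inside the phase-locking passband carrying a
  12-fold-amplified frequency sensitivity — a pure sampling artifact that
  inflates high-frequency Fisher information and breaks step-halving
  convergence.  At 500 kHz the folded harmonics are of high enough order
  (k ≳ 36) to be negligible at the tested levels.  Mean-rate quantities
  (thresholds, excitation patterns) are insensitive to this and keep the
  cheaper rate.
- **Finite-difference steps.**  Frequency-like steps are absolute —
  0.25 Hz for FDL, 0.025 Hz for F0DL — because the validity scale is the
  accumulated phase excursion 2π·n_harm·h·T over the 100-ms stimulus
  (n_harm up to ~11 for the filtered HCT), which does not scale with
  frequency.  Level steps are 0.25 dB and phase steps 1°.  Halving the
  frequency steps changes the anchor-frequency JNDs by < 0.2% (< 1% at
  1.4 kHz F0); JNDs at the extreme high end of the FDL grid (≳ 12 kHz)
  retain a few-percent step sensitivity from residual fold products and
  should be read accordingly.
- **Smoothness of the rate map.**  The retained-harmonic set and the
  bandpass filter of the F0DL stimulus are frozen at the nominal F0 across
  derivative evaluations, so the waveform is a smooth function of θ;
  letting set membership follow θ would inject discrete jumps into the
  finite differences.
- **Rates are bounded below** by the spontaneous rate by construction, so
  the 1/r_i weight in the Fisher integrand is always finite.
- **ML oracle.**  Implemented as a two-interval forced choice: each trial
  draws one observation from the baseline intensity and one from the
  incremented intensity and attributes the increment to the interval with
  the larger Poisson log-likelihood.  Per-bin spike counts on the
  simulation grid are a sufficient statistic for the likelihood ratio with
  piecewise-constant intensity.  At Δ = the CRLB JND (d′ = 1) this
  observer scores ≈ 0.75, bracketing the 70.7%-correct convention; spike
  *times* for the sample type are drawn by thinning.
- **LOESS evaluation** refuses extrapolation outside the grid span, and
  interpolation points are sorted before evaluation (a requirement of the
  smoother's interface).

## What the synthetic stimuli do and do not capture

The stimulus module *is* the study's data generator: thresholds are
properties of the model, not of recorded data, so "passing" means the
pipeline reproduces the model-family behavior, not that humans behave this
way.  The synthesized stimuli match the simulation protocols (durations,
ramps, filter orders, rove widths, masker geometries) but the front end
omits middle-ear filtering, cochlear compression and suppression, synaptic
adaptation, and efferent feedback.  Consequences visible in the results:
absolute ideal-observer thresholds are orders of magnitude better than
human performance (as expected for unbiased-estimator bounds on the full
spike pattern), and envelope modulations up to ~2 kHz survive the
phase-locking cascade undamped by any synaptic dynamics.

## Known limitations

- The all-information F0DL ratio between F0 = 1.4 kHz and 0.28 kHz is
  ≈ 3.3 in this front end — at the lower end of the range published
  model families span (≈ 3 to > 10).  The cause is structural: at
  F0 = 1.4 kHz the all-information observer exploits envelope beats at F0
  between partially resolved harmonics, and a cascade of identical
  first-order lowpass stages cannot strongly attenuate a 1.4-kHz envelope
  while preserving 2–2.8-kHz fine structure.  Models with synaptic
  adaptation limit high-rate envelope coding further; adaptation is
  outside this package's scope.
- The rate-place F0DL ratio is ≈ 0.83 rather than exactly 1: the
  Glasberg–Moore Q_ERB rises by ~8% across the relevant CF range
  (better relative tuning, hence slightly better rate-place thresholds at
  high F0), with a small additional contribution from phase-locked AC
  interacting with the rate floor and ceiling at low F0.  "Flat or
  slightly improving with frequency" is the expected regime.
- Ideal-observer analysis is not applied to masked (GEOM/DBL) stimuli:
  exact-template observers exploit trial-unpredictable target–masker
  interactions and produce unrealistically good thresholds; the masked
  configurations are analyzed through excitation patterns and
  autocorrelograms instead.
- At 50 dB SPL per component, HSR saturation to within 10% of the maximum
  rate holds where phase locking is absent (high-frequency components);
  at low CFs the phase-locked rate necessarily dips each cycle and the
  time-averaged rate sits ~15–20% below the ceiling.

## Population views

Excitation patterns average the time-averaged rate over repeated
syntheses (default 10) with fresh ±3 dB level roves and fresh TEN, on 200
log-spaced CFs spanning 4–12 × F0, and report mean ± SD across repeats
(the SD describes stimulus-draw variability; it is not a standard error
and does not shrink with more repeats).  Autocorrelograms use linearly
spaced CFs over the same span; each channel's rate is mean-subtracted and
variance-normalized so acf(0) = 1 (a constant channel degenerates to the
flat convention acf ≡ 1), and the summary autocorrelation (sACF) is the
sum across CFs.  The temporal-cue salience scalar is the sACF at the
target-period lag relative to the local median over [0.5, 1.5] × period;
it is ≈ 0 for a flat sACF, grows with target-to-masker ratio for the DBL
configuration, and is an order of magnitude larger for a 280-Hz than for
a 1400-Hz complex.
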