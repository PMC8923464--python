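# anpitch

Auditory-nerve population modeling and ideal-observer analysis of pure-tone
frequency discrimination and fundamental-frequency (F0) discrimination.

## The problem

Human pitch discrimination degrades at high frequencies: pure-tone frequency
difference limens (FDLs) worsen steeply above 2–3 kHz, and F0 difference
limens (F0DLs) for harmonic complex tones (HCTs) are several times poorer
when all components lie above ~8 kHz than at lower frequencies.  Whether
these limits reflect the rolloff of phase locking to temporal fine structure
(TFS) in the auditory nerve, or the precision of a tonotopic rate-place
code, is a long-standing question.  `anpitch` addresses it the way
computational auditory neuroscience does: simulate the instantaneous firing
rates r_i(t, θ) of a population of model auditory-nerve fibers in response
to parametric stimuli, and ask how well *any* unbiased decoder of the
population's Poisson spike trains could discriminate the stimulus parameter
θ (frequency or F0).

## The model

Spike trains are inhomogeneous Poisson processes with conditionally
independent fibers, so the Fisher information about the parameter vector
**θ** is

    I(θ)[α,β] = Σ_i K_i ∫₀ᵀ (1/r_i) (∂r_i/∂θ_α)(∂r_i/∂θ_β) dt,

with K_i fibers sharing each simulated characteristic frequency (CF).
Randomly roved stimulus parameters (component levels, phases) are handled
by averaging I(θ) over the rove distribution and adding a diagonal prior
information matrix A(θ) with entries 1/ν²; the variance of the best
unbiased estimate of the target parameter is bounded by the Cramér–Rao
inequality

    var(θ̂₁) ≥ [(E_θ[I(θ)] + A(θ))⁻¹]₁₁,

and the just-noticeable difference (JND) at the 70.7%-correct point is the
square root of that bound.  Two observers are compared: the
**all-information** observer uses the full spatiotemporal rate pattern; the
**rate-place** observer first replaces each fiber's rate by its time
average.  A Monte-Carlo maximum-likelihood 2AFC classifier over sampled
spike trains provides an independent check that the bound sits near the
70.7% point.

The reference front end is an analytic chain: gammatone filterbank with
human (Glasberg–Moore ERB) bandwidths → half-wave-rectifying saturating
transduction → cascade of first-order lowpass stages that limits phase
locking above ~2.5 kHz → affine map to rate between the fiber's spontaneous
rate and its maximum rate.  High-, medium- and low-spontaneous-rate fiber
classes differ in sensitivity and saturation.  Other rate-based nerve
models can be plugged in behind the same `simulate_rates` contract.
Stimuli (pure tones, discrete and bandpass-filtered HCTs,
threshold-equalizing noise, GEOM/DBL complex-tone maskers, with seeded
level roving and phase randomization) are synthesized by the package; no
external data are required.

## Worked example

Simulated pure-tone FDLs near 2 kHz at 30 dB above the model's rate-level
threshold, for a population of 40 CFs × 72 fibers:

```python
import numpy as np
from anpitch import experiments, frontend

front = frontend.HeinzFrontend()
thresholds = frontend.calibrate_rate_level_thresholds(front)

grid = experiments.ExperimentGrid("FDL", np.array([1900.0, 2000.0, 2100.0]))
curve = experiments.run_fdl(grid, front, thresholds, seed=0)
print(curve[["frequency", "observer", "jnd_hz", "jnd_pct"]].round(4).to_string(index=False))
```

prints

```
 frequency        observer  jnd_hz  jnd_pct
    1900.0 all_information  0.0635   0.0033
    1900.0      rate_place  4.1007   0.2158
    2000.0 all_information  0.0653   0.0033
    2000.0      rate_place  4.2985   0.2149
    2100.0 all_information  0.0672   0.0032
    2100.0      rate_place  4.4956   0.2141
```

The all-information observer (full spike timing) predicts FDLs of about
0.003% — some 65× better than the rate-place observer at the same place in
the cochlea, reflecting the potency of phase-locked TFS at 2 kHz.  Both
are far better than human listeners (~0.2% behaviorally): the interest is
in how the bound *changes* with frequency, not its absolute value.

A command-line interface exposes the same pipelines
(`anpitch calibrate | fdl | f0dl | excitation | acg | stim-export`), each
writing CSV/JSON artifacts plus a run manifest with the seed and front-end
configuration.

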