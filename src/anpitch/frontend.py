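"""Phenomenological auditory-nerve front end.

The reference model is an analytic chain in the spirit of classic
filterbank/transduction nerve models: a level-calibrated gammatone
bandpass filter at each characteristic frequency (CF) with human ERB
bandwidths, a half-wave-rectifying saturating transduction from pressure
to inner-hair-cell drive, a cascade of first-order lowpass stages that
limits phase locking at high frequencies, and a saturating synapse mapping
drive to instantaneous firing rate between the fiber's spontaneous rate
and its maximum rate.  The output is the *expected* (noise-free) rate
r_i(t); Poisson variability enters only in the observer machinery.

Fiber classes differ in spontaneous rate and input sensitivity:
high-spontaneous-rate (HSR) fibers have low thresholds and saturate at
moderate levels, low-spontaneous-rate (LSR) fibers have higher thresholds
and a wide dynamic range, with medium (MSR) fibers in between.

A plug-in registry lets other rate-based nerve models be substituted for
the reference chain; everything downstream (ideal observer, experiments,
population views) only sees the ``simulate_rates`` contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

from .stimuli import Waveform, ToneSpec, erb_hz, synth_pure_tone

__all__ = [
    "FiberSpec",
    "PopulationSpec",
    "RateResponse",
    "RateLevelThresholdMap",
    "FrontendConfig",
    "HeinzFrontend",
    "calibrate_rate_level_thresholds",
    "level_re_threshold",
    "vector_strength",
    "q10",
    "register_frontend",
    "get_frontend",
]

_CLASS_DEFAULTS = {
    # (spont sp/s, input gain dB re: HSR)
    "HSR": (60.0, 0.0),
    "MSR": (18.0, -12.0),
    "LSR": (1.0, -25.0),
}


@dataclass(frozen=True)
class FiberSpec:
    """A single model fiber: CF, class, and rate parameters."""

    cf: float
    fiber_class: str = "HSR"
    spont: float = 60.0
    max_rate: float = 300.0

    def __post_init__(self):
        if self.cf <= 0:
            raise ValueError("cf must be positive")
        if not (0 < self.spont < self.max_rate):
            raise ValueError("require 0 < spont < max_rate")


@dataclass(frozen=True)
class PopulationSpec:
    """A CF grid with a fibers-per-CF multiplier.

    ``fibers_per_cf`` fibers with nearby CFs are assumed to share the rate
    pattern simulated at each grid CF, so the grid approximates a much
    larger underlying population.  ``composition`` records the assumed
    HSR/MSR/LSR split of the whole nerve (used to size per-class counts).
    """

    cf_grid: np.ndarray
    fibers_per_cf: int = 1
    fiber_class: str = "HSR"
    composition: tuple = (0.6, 0.2, 0.2)

    def __post_init__(self):
        grid = np.atleast_1d(np.asarray(self.cf_grid, dtype=float))
        if np.any(np.diff(grid) <= 0):
            raise ValueError("cf_grid must be strictly increasing")
        if self.fibers_per_cf < 1:
            raise ValueError("fibers_per_cf must be >= 1")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        object.__setattr__(self, "cf_grid", grid)

    @staticmethod
    def log_spaced(lo: float, hi: float, n: int, **kwargs) -> "PopulationSpec":
        return PopulationSpec(np.geomspace(lo, hi, n), **kwargs)


@dataclass
class RateResponse:
    """Instantaneous firing rate for a population of fibers.

    ``rates`` is (n_cf, n_time) in spikes/s on ``time`` (s);
    ``fibers_per_cf`` is the population multiplier carried into the
    Fisher-information sum.
    """

    rates: np.ndarray
    time: np.ndarray
    cf_grid: np.ndarray
    fibers_per_cf: int = 1
    stimulus_params: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + float(self.time[1] - self.time[0])

    def time_averaged(self) -> np.ndarray:
        return self.rates.mean(axis=1)


@dataclass(frozen=True)
class FrontendConfig:
    """Reference front-end parameters.

    tuning : ``"glasberg_moore"`` (human ERB, Q_ERB rising from ~8.4 to
        ~9.2 over 2–20 kHz) or ``"shera"`` (power law
        Q_ERB = q0 (CF/1 kHz)^q_exp, sharper at high CF).
    pl_cutoff, pl_order : composite −3 dB cutoff (Hz) and number of
        first-order lowpass stages limiting phase locking (the per-stage
        cutoff is derived so the cascade reaches −3 dB at ``pl_cutoff``);
        calibrated so on-CF vector strength starts declining near 2–3 kHz
        and is negligible above ~8–10 kHz.
    p_sat : half-saturation pressure (Pa) of the hair-cell transduction.
    syn_gain : affine synapse gain (spikes/s per unit drive); with the
        transduction scale it places the HSR rate-level threshold (5%
        above spont) near 0 dB SPL and the saturation knee near 35-40 dB
        SPL, so HSR fibers are saturated by ~50 dB SPL.
    """

    tuning: str = "glasberg_moore"
    q0: float = 12.7
    q_exp: float = 0.3
    gamma_order: int = 4
    pl_cutoff: float = 2500.0
    pl_order: int = 7
    p_sat: float = 0.05
    syn_gain: float = 16_000.0
    max_rate: float = 300.0
    class_params: dict = field(default_factory=lambda: dict(_CLASS_DEFAULTS))

    def erb_at(self, cf: float | np.ndarray) -> np.ndarray:
        if self.tuning == "glasberg_moore":
            return erb_hz(cf)
        cf = np.asarray(cf, dtype=float)
        q = self.q0 * (cf / 1000.0) ** self.q_exp
        return cf / q

    def q_erb(self, cf: float | np.ndarray) -> np.ndarray:
        return np.asarray(cf, dtype=float) / self.erb_at(cf)


class HeinzFrontend:
    """Reference analytic-chain front end (see module docstring)."""

    def __init__(self, config: FrontendConfig | None = None):
        self.config = config or FrontendConfig()

    # -- linear stage -------------------------------------------------

    def gammatone_gain(self, cf: float, freqs: np.ndarray, sample_rate: float) -> np.ndarray:
        """Magnitude response of the CF channel's gammatone filter,
        normalized to unity at CF (evaluated from the digital filter)."""
        b_coef, a_pole = self._gamma_coefs(cf, sample_rate)
        w = 2 * np.pi * np.atleast_1d(np.asarray(freqs, float)) / sample_rate
        z = np.exp(1j * w)
        h = (b_coef / (1.0 - a_pole / z)) ** self.config.gamma_order
        w_cf = 2 * np.pi * cf / sample_rate
        h_cf = (b_coef / (1.0 - a_pole * np.exp(-1j * w_cf))) ** self.config.gamma_order
        return np.abs(h) / np.abs(h_cf)

    def _gamma_coefs(self, cf: float, sample_rate: float):
        # bandwidth parameter set so the order-n gammatone's ERB matches the
        # tuning law: ERB = b * sqrt(pi) * Gamma(n - 1/2) / Gamma(n)
        n = self.config.gamma_order
        factor = np.sqrt(np.pi) * special.gamma(n - 0.5) / special.gamma(n)
        bw = float(self.config.erb_at(cf)) / factor
        dt = 1.0 / sample_rate
        a_pole = np.exp(-2 * np.pi * bw * dt) * np.exp(1j * 2 * np.pi * cf * dt)
        return (1.0 - np.abs(a_pole)), a_pole

    def _basilar(self, pressure: np.ndarray, cf: float, sample_rate: float) -> np.ndarray:
        b_coef, a_pole = self._gamma_coefs(cf, sample_rate)
        y = pressure.astype(complex)
        for _ in range(self.config.gamma_order):
            y = signal.lfilter([b_coef], [1.0, -a_pole], y)
        # demodulated complex output; project back and normalize CF gain to 1
        w_cf = 2 * np.pi * cf / sample_rate
        h_cf = (b_coef / (1.0 - a_pole * np.exp(-1j * w_cf))) ** self.config.gamma_order
        return np.real(y) * 2.0 / np.abs(h_cf)

    # -- nonlinear stages ---------------------------------------------

    def _transduce(self, x: np.ndarray, gain_db: float) -> np.ndarray:
        u = np.maximum(10.0 ** (gain_db / 20.0) * x, 0.0) / self.config.p_sat
        return u / (1.0 + u)

    def pl_stage_cutoff(self) -> float:
        """Per-stage first-order cutoff giving a composite −3 dB point at
        ``pl_cutoff`` for the ``pl_order``-stage cascade."""
        cfg = self.config
        return cfg.pl_cutoff / np.sqrt(2.0 ** (1.0 / cfg.pl_order) - 1.0)

    def _pl_lowpass(self, s: np.ndarray, sample_rate: float) -> np.ndarray:
        a = np.exp(-2 * np.pi * self.pl_stage_cutoff() / sample_rate)
        for _ in range(self.config.pl_order):
            s = signal.lfilter([1.0 - a], [1.0, -a], s)
        return s

    def _synapse(self, v: np.ndarray, spont: float) -> np.ndarray:
        # affine map to rate with floor spont and ceiling max_rate
        cfg = self.config
        driven = np.clip(cfg.syn_gain * v, 0.0, cfg.max_rate - spont)
        return spont + driven

    # -- public API ---------------------------------------------------

    def simulate_rates(self, stimulus: Waveform, population: PopulationSpec) -> RateResponse:
        """Deterministic instantaneous rate for every CF in the population."""
        cfg = self.config
        fs = stimulus.sample_rate
        if np.any(population.cf_grid >= fs / 2):
            raise ValueError("CF at or above Nyquist frequency")
        spont, gain_db = self._class_params(population.fiber_class)
        rates = np.empty((len(population.cf_grid), len(stimulus.samples)))
        for i, cf in enumerate(population.cf_grid):
            x = self._basilar(stimulus.samples, cf, fs)
            s = self._transduce(x, gain_db)
            v = self._pl_lowpass(s, fs)
            rates[i] = self._synapse(v, spont)
        return RateResponse(
            rates=rates,
            time=stimulus.time,
            cf_grid=population.cf_grid.copy(),
            fibers_per_cf=population.fibers_per_cf,
        )

    def _class_params(self, fiber_class: str):
        try:
            spont, gain_db = self.config.class_params[fiber_class]
        except KeyError:
            raise ValueError(f"unknown fiber class {fiber_class!r}") from None
        return spont, gain_db

    def spont_rate(self, fiber_class: str = "HSR") -> float:
        return self._class_params(fiber_class)[0]


# ---------------------------------------------------------------------------
# rate-level threshold calibration


@dataclass
class RateLevelThresholdMap:
    """Pure-tone rate-level thresholds (dB SPL) versus frequency, linearly
    interpolated in (frequency, dB)."""

    freqs: np.ndarray
    thresholds: np.ndarray
    flagged: np.ndarray

    def __call__(self, freq: float | np.ndarray) -> np.ndarray:
        freq = np.asarray(freq, dtype=float)
        if np.any(freq < self.freqs[0]) or np.any(freq > self.freqs[-1]):
            raise ValueError("frequency outside calibrated range")
        return np.interp(freq, self.freqs, self.thresholds)


def calibrate_rate_level_thresholds(
    frontend,
    freqs: np.ndarray | None = None,
    levels: np.ndarray | None = None,
    duration: float = 0.1,
    sample_rate: float = 100_000.0,
    criterion: float = 1.05,
    fiber_class: str = "HSR",
) -> RateLevelThresholdMap:
    """Rate-level threshold map for on-CF fibers.

    For each frequency on a 25-point log grid (0.2–20 kHz), 100-ms pure
    tones are simulated across a 25-point level grid (−10 to 40 dB SPL);
    the rate-level function is linearly interpolated and the minimum level
    evoking a mean rate ``criterion`` × spont is recorded.  If no grid
    level reaches criterion the grid maximum is recorded with a warning
    flag.
    """
    if freqs is None:
        freqs = np.geomspace(200.0, 20_000.0, 25)
    if levels is None:
        levels = np.linspace(-10.0, 40.0, 25)
    spont = frontend.spont_rate(fiber_class)
    target = criterion * spont
    thresholds = np.empty(len(freqs))
    flagged = np.zeros(len(freqs), dtype=bool)
    for i, f in enumerate(freqs):
        pop = PopulationSpec(np.array([f]), fiber_class=fiber_class)
        mean_rates = np.empty(len(levels))
        for j, level in enumerate(levels):
            spec = ToneSpec(kind="pure", f_or_f0=f, component_levels=(level,), duration=duration)
            resp = frontend.simulate_rates(synth_pure_tone(spec, sample_rate), pop)
            mean_rates[j] = resp.time_averaged()[0]
        if mean_rates[-1] < target:
            thresholds[i] = levels[-1]
            flagged[i] = True
            warnings.warn(f"rate-level criterion not reached at {f:.0f} Hz", stacklevel=2)
        else:
            k = int(np.argmax(mean_rates >= target))
            if k == 0:
                thresholds[i] = levels[0]
            else:
                # linear interpolation of the rate-level function
                thresholds[i] = np.interp(
                    target, mean_rates[k - 1 : k + 1], levels[k - 1 : k + 1]
                )
    return RateLevelThresholdMap(np.asarray(freqs, float), thresholds, flagged)


def level_re_threshold(freq: float, db_re_thr: float, thr_map: RateLevelThresholdMap) -> float:
    """Absolute presentation level (dB SPL) for a level expressed relative
    to the rate-level threshold at ``freq``."""
    return float(thr_map(freq)) + db_re_thr


# ---------------------------------------------------------------------------
# diagnostics


def vector_strength(rate: np.ndarray, time: np.ndarray, freq: float) -> float:
    """Vector strength of a rate waveform at ``freq``.

    |∫ r(t) e^{−i 2π f t} dt| / ∫ r(t) dt over an integer number of cycles.
    """
    dt = time[1] - time[0]
    duration = len(time) * dt
    n_cycles = int(np.floor(duration * freq))
    if n_cycles < 5:
        raise ValueError("duration must cover at least 5 cycles")
    n_keep = int(round(n_cycles / freq / dt))
    r = rate[:n_keep]
    t = time[:n_keep]
    # rectangle rule: exact phase cancellation over integer cycles
    total = float(np.sum(r) * dt)
    if total <= 0:
        raise ZeroDivisionError("zero integrated rate: vector strength undefined")
    num = np.abs(np.sum(r * np.exp(-1j * 2 * np.pi * freq * t)) * dt)
    return float(num / total)


def q10(
    frontend,
    cf: float,
    probe_level: float = 20.0,
    sample_rate: float = 100_000.0,
    n_probe: int = 161,
    span_octaves: float = 1.0,
    fiber_class: str = "HSR",
    probe_duration: float = 0.2,
) -> float:
    """Tuning sharpness Q10 from iso-level probe-tone responses.

    Probe tones are swept around CF at fixed level; the driven rate at each
    probe frequency is converted to an equivalent input attenuation by
    inverting the on-CF rate-level function, and Q10 = CF / (bandwidth at
    10 dB equivalent attenuation).  Long probes (default 200 ms) keep the
    probe's own spectral spread narrow relative to low-CF filters.
    """
    freqs = np.geomspace(cf * 2 ** (-span_octaves / 2), cf * 2 ** (span_octaves / 2), n_probe)
    freqs = freqs[freqs < sample_rate / 2 * 0.95]
    spont = frontend.spont_rate(fiber_class)
    pop = PopulationSpec(np.array([cf]), fiber_class=fiber_class)

    def driven(f: float, level: float) -> float:
        spec = ToneSpec(kind="pure", f_or_f0=f, component_levels=(level,), duration=probe_duration)
        resp = frontend.simulate_rates(synth_pure_tone(spec, sample_rate), pop)
        return float(resp.time_averaged()[0] - spont)

    # on-CF rate-level function over the attenuation range of interest
    ref_levels = np.linspace(probe_level - 25.0, probe_level, 51)
    ref_driven = np.array([driven(cf, L) for L in ref_levels])
    if np.any(np.diff(ref_driven) <= 0):
        raise ValueError("on-CF rate-level function not monotone at this level")
    resp_curve = np.array([driven(f, probe_level) for f in freqs])
    i_peak = int(np.argmax(resp_curve))
    if i_peak == 0 or i_peak == len(freqs) - 1:
        raise ValueError("iso-level response not unimodal over the probe span")
    atten = probe_level - np.interp(
        np.clip(resp_curve, ref_driven[0], ref_driven[-1]), ref_driven, ref_levels
    )

    def crossing(side: slice, reverse: bool) -> float:
        a = atten[side]
        f = freqs[side]
        if reverse:
            a, f = a[::-1], f[::-1]
        for k in range(len(a) - 1):
            if a[k] <= 10.0 < a[k + 1]:
                return float(np.interp(10.0, [a[k], a[k + 1]], [f[k], f[k + 1]]))
        raise ValueError("10-dB-down point outside probe span")

    f_hi = crossing(slice(i_peak, None), reverse=False)
    f_lo = crossing(slice(None, i_peak + 1), reverse=True)
    bw = f_hi - f_lo
    if bw <= 0:
        raise ValueError("non-positive 10-dB bandwidth")
    return float(cf / bw)


# ---------------------------------------------------------------------------
# plug-in registry

_REGISTRY: dict[str, object] = {}


def register_frontend(name: str, frontend, probe_sample_rate: float = 50_000.0):
    """Register a front-end adapter after validating its contract with a
    probe stimulus (shape match, finite nonnegative rates)."""
    probe = synth_pure_tone(
        ToneSpec(kind="pure", f_or_f0=1000.0, component_levels=(30.0,), duration=0.05),
        probe_sample_rate,
    )
    pop = PopulationSpec(np.array([800.0, 1000.0, 1250.0]))
    resp = frontend.simulate_rates(probe, pop)
    rates = np.asarray(resp.rates)
    if rates.shape != (len(pop.cf_grid), len(probe.samples)):
        raise ValueError("adapter returned rates with mismatched shape")
    if not np.all(np.isfinite(rates)):
        raise ValueError("adapter returned non-finite rates")
    if np.any(rates < 0):
        raise ValueError("adapter returned negative rates")
    _REGISTRY[name] = frontend
    return frontend


def get_frontend(name: str):
    return _REGISTRY[name]
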