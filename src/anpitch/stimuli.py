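"""Parametric synthesis of the acoustic stimuli used in the simulations.

All stimuli are calibrated sound-pressure waveforms in pascals: a pure tone
at level L dB SPL has RMS pressure 20 µPa * 10^(L/20).  The classes here are
the pipeline's synthetic-data generators — pure tones, harmonic complex
tones (HCTs, discrete harmonics or bandpass-filtered), threshold-equalizing
noise (TEN), and the GEOM/DBL complex-tone masker mixtures — with seeded
per-component level roving and phase randomization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

#: Reference pressure for dB SPL (Pa).
P_REF = 20e-6

#: Default simulation sample rate (Hz).
DEFAULT_FS = 100_000.0


def db_spl_to_rms(level_db: float | np.ndarray) -> np.ndarray:
    """RMS pressure (Pa) of a tone at ``level_db`` dB SPL."""
    return P_REF * 10.0 ** (np.asarray(level_db, dtype=float) / 20.0)


def erb_hz(f_hz: float | np.ndarray) -> np.ndarray:
    """Equivalent rectangular bandwidth (Hz) of the human auditory filter.

    Glasberg–Moore formula ERB(f) = 24.7 (4.37 f_kHz + 1).
    """
    f_khz = np.asarray(f_hz, dtype=float) / 1000.0
    return 24.7 * (4.37 * f_khz + 1.0)


def semitones_to_ratio(st: float) -> float:
    """Frequency ratio corresponding to a semitone offset (2^(ST/12))."""
    return float(2.0 ** (st / 12.0))


@dataclass(frozen=True)
class Waveform:
    """A calibrated sound-pressure time series.

    Attributes
    ----------
    samples : ndarray
        Instantaneous pressure in Pa.
    sample_rate : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def level_db_spl(self) -> float:
        return float(20.0 * np.log10(self.rms() / P_REF))

    def __add__(self, other: "Waveform") -> "Waveform":
        if other.sample_rate != self.sample_rate:
            raise ValueError("sample rates differ")
        if len(other.samples) != len(self.samples):
            raise ValueError("lengths differ")
        return Waveform(self.samples + other.samples, self.sample_rate)


@dataclass(frozen=True)
class ToneSpec:
    """Parameters of a pure tone or harmonic complex tone.

    ``kind`` is one of ``pure``, ``hct_discrete`` (explicit harmonic
    numbers) or ``hct_filtered`` (all harmonics to Nyquist, then a
    zero-phase Butterworth bandpass at ``filter_cutoffs`` times the nominal
    F0).  ``component_levels`` (dB SPL) and ``component_phases`` (radians)
    are per component; scalars broadcast.
    """

    kind: str
    f_or_f0: float
    harmonics: tuple = (1,)
    component_levels: tuple = (50.0,)
    component_phases: tuple = (0.0,)
    duration: float = 0.1
    ramp: float = 0.01
    filter_cutoffs: tuple = (5.5, 10.5)
    filter_order: int = 12

    def __post_init__(self):
        if self.kind not in ("pure", "hct_discrete", "hct_filtered"):
            raise ValueError(f"unknown tone kind {self.kind!r}")
        if self.f_or_f0 <= 0:
            raise ValueError("frequency/F0 must be positive")
        harmonics = tuple(int(h) for h in np.atleast_1d(self.harmonics))
        if any(h < 1 for h in harmonics):
            raise ValueError("harmonic numbers must be >= 1")
        if any(b <= a for a, b in zip(harmonics, harmonics[1:])):
            raise ValueError("harmonic numbers must be strictly increasing")
        if self.duration <= 2 * self.ramp:
            raise ValueError("duration must exceed twice the ramp time")
        object.__setattr__(self, "harmonics", harmonics)

    def n_components(self) -> int:
        return len(self.harmonics)

    def levels_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.component_levels, float)),
            (len(self.harmonics),),
        ).copy()

    def phases_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.component_phases, float)),
            (len(self.harmonics),),
        ).copy()

    def replace(self, **kwargs) -> "ToneSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class RoveSpec:
    """Level roving and phase randomization parameters.

    Synthesis draws are uniform: levels on ±``level_halfwidth`` dB, phases
    over ``phase_range`` degrees.  The observer math instead treats roved
    parameters with normal-approximation priors of SD ``eval_level_sd`` /
    ``eval_phase_sd`` (the synthesis/evaluation asymmetry keeps the Fisher
    information well defined for the uniform rove).
    """

    level_halfwidth: float = 3.0
    phase_range: float = 360.0
    eval_level_sd: float = 6.0
    eval_phase_sd: float = 360.0

    def __post_init__(self):
        if self.level_halfwidth < 0 or self.phase_range < 0:
            raise ValueError("rove halfwidths must be nonnegative")


@dataclass(frozen=True)
class NoiseSpec:
    """Threshold-equalizing noise, specified by its level (dB SPL) within
    the ERB of the auditory filter centered on 1 kHz."""

    level_in_erb_1k: float = 40.0
    lead_lag: float = 0.0
    ramp: float = 0.01

    def __post_init__(self):
        if not np.isfinite(self.level_in_erb_1k):
            raise ValueError("TEN level must be finite")
        if self.lead_lag < 0:
            raise ValueError("lead_lag must be nonnegative")


@dataclass(frozen=True)
class MaskerSpec:
    """Complex-tone masker configuration.

    GEOM: a single masker at the geometric mean of the reference and target
    F0s, bandpass-filtered more broadly (4–12 × nominal F0) or, in the
    discrete variant, extended to harmonics 5–11.  DBL: two maskers
    flanking the target F0 by semitone offsets of opposite sign.
    ``tmr`` is the target-to-masker ratio in dB (masker level = target
    level − tmr).
    """

    masker_kind: str
    masker_f0s: tuple
    tmr: float = 0.0
    filter_cutoffs: tuple = (4.0, 12.0)
    semitone_offsets: tuple = ()

    def __post_init__(self):
        if self.masker_kind not in ("GEOM", "DBL"):
            raise ValueError(f"unknown masker kind {self.masker_kind!r}")
        f0s = tuple(float(f) for f in np.atleast_1d(self.masker_f0s))
        if self.masker_kind == "GEOM" and len(f0s) != 1:
            raise ValueError("GEOM masker has exactly one F0")
        if self.masker_kind == "DBL":
            if len(f0s) != 2:
                raise ValueError("DBL masker has exactly two F0s")
            if len(self.semitone_offsets) == 2:
                if np.sign(self.semitone_offsets[0]) == np.sign(self.semitone_offsets[1]):
                    raise ValueError("DBL offsets must have opposite sign")
        object.__setattr__(self, "masker_f0s", f0s)


def geom_masker_f0(f0_reference: float, f0_target: float) -> float:
    """Geometric-mean masker F0 for the GEOM condition."""
    return float(np.sqrt(f0_reference * f0_target))


def dbl_masker_f0s(f0_target: float, st_below: float = 5.5, st_above: float = 6.0) -> tuple:
    """DBL masker F0s: one ``st_below`` semitones below and one
    ``st_above`` above the target F0."""
    return (
        f0_target * semitones_to_ratio(-abs(st_below)),
        f0_target * semitones_to_ratio(abs(st_above)),
    )


# ---------------------------------------------------------------------------
# synthesis


def _raised_cosine_ramp(n_total: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n_total)
    if n_ramp > 0:
        # endpoints exactly 0, full-scale reached at sample n_ramp
        t = np.arange(n_ramp) / n_ramp
        ramp = 0.5 * (1.0 - np.cos(np.pi * t))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def _check_nyquist(freq: float, sample_rate: float):
    if freq >= sample_rate / 2:
        raise ValueError(
            f"component frequency {freq:.1f} Hz is at or above the Nyquist "
            f"frequency {sample_rate / 2:.1f} Hz"
        )


def _component_sum(
    freqs: np.ndarray,
    levels: np.ndarray,
    phases: np.ndarray,
    duration: float,
    sample_rate: float,
) -> np.ndarray:
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    amps = db_spl_to_rms(levels) * np.sqrt(2.0)
    # sine convention: zero starting phase -> first sample 0
    return (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(
        axis=0
    )


def synth_pure_tone(spec: ToneSpec, sample_rate: float = DEFAULT_FS) -> Waveform:
    """Synthesize a calibrated, ramped pure tone (sine phase convention)."""
    if spec.kind != "pure":
        raise ValueError("spec.kind must be 'pure'")
    _check_nyquist(spec.f_or_f0, sample_rate)
    x = _component_sum(
        np.array([spec.f_or_f0]),
        spec.levels_array()[:1],
        spec.phases_array()[:1],
        spec.duration,
        sample_rate,
    )
    n_ramp = int(round(spec.ramp * sample_rate))
    return Waveform(x * _raised_cosine_ramp(len(x), n_ramp), sample_rate)


def synth_hct(spec: ToneSpec, sample_rate: float = DEFAULT_FS) -> Waveform:
    """Synthesize an HCT from an explicit harmonic set; ramps applied after
    summation."""
    if spec.kind != "hct_discrete":
        raise ValueError("spec.kind must be 'hct_discrete'")
    freqs = np.asarray(spec.harmonics, float) * spec.f_or_f0
    for f in freqs:
        _check_nyquist(f, sample_rate)
    x = _component_sum(freqs, spec.levels_array(), spec.phases_array(), spec.duration, sample_rate)
    n_ramp = int(round(spec.ramp * sample_rate))
    return Waveform(x * _raised_cosine_ramp(len(x), n_ramp), sample_rate)


def bandpass_sos(
    f0_nominal: float,
    sample_rate: float,
    cutoffs: tuple = (5.5, 10.5),
    order: int = 12,
):
    """Second-order sections of the Butterworth bandpass used for filtered
    HCTs (a 12-pole design, applied forward and backward downstream)."""
    lo = cutoffs[0] * f0_nominal
    hi = cutoffs[1] * f0_nominal
    if lo <= 0 or hi >= sample_rate / 2:
        raise ValueError("bandpass cutoffs outside (0, Nyquist)")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def bandpass_gain_db(
    freqs: np.ndarray,
    f0_nominal: float,
    sample_rate: float,
    cutoffs: tuple = (5.5, 10.5),
    order: int = 12,
) -> np.ndarray:
    """Magnitude response (dB) of the zero-phase (forward-backward)
    bandpass at ``freqs``; the squared-magnitude of the one-pass design."""
    sos = bandpass_sos(f0_nominal, sample_rate, cutoffs, order)
    w, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=sample_rate)
    mag = np.abs(h)
    return 20.0 * np.log10(np.maximum(mag, 1e-300)) * 2.0  # two passes


def filtered_hct_harmonics(
    f0_nominal: float,
    sample_rate: float,
    cutoffs: tuple = (5.5, 10.5),
    order: int = 12,
    max_attenuation_db: float = 100.0,
) -> np.ndarray:
    """Harmonic numbers retained for a filtered HCT: all harmonics to
    Nyquist whose post-filter attenuation is below ``max_attenuation_db``
    (deeper components are numerically indistinguishable from absent)."""
    n_max = int(np.floor((sample_rate / 2 - 1.0) / f0_nominal))
    hs = np.arange(1, n_max + 1)
    gains = bandpass_gain_db(hs * f0_nominal, f0_nominal, sample_rate, cutoffs, order)
    keep = gains > -max_attenuation_db
    if not np.any(keep):
        raise ValueError("no harmonic within the filter passband")
    return hs[keep]


def synth_filtered_hct(
    spec: ToneSpec,
    sample_rate: float = DEFAULT_FS,
    f0_filter: float | None = None,
    retained_harmonics: np.ndarray | None = None,
) -> Waveform:
    """Synthesize an HCT with all harmonics to Nyquist, then apply the
    zero-phase Butterworth bandpass at ``filter_cutoffs`` × nominal F0.

    ``spec.harmonics`` lists the harmonics carrying explicit per-component
    levels/phases (typically those in or near the passband); remaining
    harmonics within the retained set get the first level / zero phase.
    ``f0_filter`` anchors the bandpass to a nominal F0 different from the
    synthesized F0 (reference and target tones share one filter), and
    ``retained_harmonics`` freezes the harmonic set (otherwise derived
    from the synthesized F0) — both keep the waveform a smooth function
    of F0 when it is perturbed for derivative estimates.
    """
    if spec.kind != "hct_filtered":
        raise ValueError("spec.kind must be 'hct_filtered'")
    f0 = spec.f_or_f0
    f0_filter = f0 if f0_filter is None else float(f0_filter)
    if retained_harmonics is None:
        n_max = int(np.floor((sample_rate / 2 - 1.0) / f0))
        hs_all = np.arange(1, n_max + 1)
        gains = bandpass_gain_db(
            hs_all * f0, f0_filter, sample_rate, spec.filter_cutoffs, spec.filter_order
        )
        hs = hs_all[gains > -100.0]
    else:
        hs = np.asarray(retained_harmonics, dtype=int)
        if np.any(hs * f0 >= sample_rate / 2):
            raise ValueError("retained harmonic at or above Nyquist")
    if len(hs) == 0:
        raise ValueError("no harmonic within the filter passband")
    levels = np.full(len(hs), spec.levels_array()[0])
    phases = np.zeros(len(hs))
    spec_levels = spec.levels_array()
    spec_phases = spec.phases_array()
    for j, h in enumerate(spec.harmonics):
        idx = np.nonzero(hs == h)[0]
        if len(idx):
            levels[idx[0]] = spec_levels[j]
            phases[idx[0]] = spec_phases[j]
    x = _component_sum(hs * f0, levels, phases, spec.duration, sample_rate)
    sos = bandpass_sos(f0_filter, sample_rate, spec.filter_cutoffs, spec.filter_order)
    x = signal.sosfiltfilt(sos, x)
    n_ramp = int(round(spec.ramp * sample_rate))
    return Waveform(x * _raised_cosine_ramp(len(x), n_ramp), sample_rate)


def synth_tone(spec: ToneSpec, sample_rate: float = DEFAULT_FS) -> Waveform:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "pure":
        return synth_pure_tone(spec, sample_rate)
    if spec.kind == "hct_discrete":
        return synth_hct(spec, sample_rate)
    return synth_filtered_hct(spec, sample_rate)


def synth_ten(
    spec: NoiseSpec,
    duration: float,
    sample_rate: float = DEFAULT_FS,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Threshold-equalizing noise.

    White Gaussian noise is spectrally shaped with gain 1/sqrt(ERB(f)) so
    the power passing an ERB-wide auditory filter is approximately constant
    across center frequency, then scaled so the power within the ERB at
    1 kHz matches ``spec.level_in_erb_1k`` dB SPL.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng)
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n)
    spec_f = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shape = 1.0 / np.sqrt(erb_hz(np.maximum(freqs, 20.0)))
    shaped = np.fft.irfft(spec_f * shape, n=n)
    # calibrate: power through the rectangular ERB-wide band at 1 kHz
    half_bw = erb_hz(1000.0) / 2.0
    psd_band = np.abs(np.fft.rfft(shaped)) ** 2
    in_band = (freqs >= 1000.0 - half_bw) & (freqs <= 1000.0 + half_bw)
    band_power = 2.0 * psd_band[in_band].sum() / n**2  # mean-square Pa^2
    target_power = db_spl_to_rms(spec.level_in_erb_1k) ** 2
    shaped *= np.sqrt(target_power / band_power)
    n_ramp = int(round(spec.ramp * sample_rate))
    return Waveform(shaped * _raised_cosine_ramp(n, n_ramp), sample_rate)


def apply_rove(
    spec: ToneSpec,
    rove: RoveSpec,
    rng: np.random.Generator | None = None,
    rove_levels: bool = True,
    rove_phases: bool = True,
) -> ToneSpec:
    """Return a new spec with roved per-component levels and/or phases.

    Each component level is perturbed by an independent uniform draw in
    ±``level_halfwidth`` dB and each phase redrawn uniformly over
    ``phase_range`` degrees; the nominal spec is untouched.
    """
    rng = np.random.default_rng(rng)
    n = spec.n_components()
    levels = spec.levels_array()
    phases = spec.phases_array()
    if rove_levels and rove.level_halfwidth > 0:
        levels = levels + rng.uniform(-rove.level_halfwidth, rove.level_halfwidth, size=n)
    if rove_phases and rove.phase_range > 0:
        half = np.deg2rad(rove.phase_range) / 2.0
        phases = phases + rng.uniform(-half, half, size=n)
    return spec.replace(component_levels=tuple(levels), component_phases=tuple(phases))


def make_masked_stimulus(
    target: ToneSpec,
    masker: MaskerSpec | None,
    noise: NoiseSpec | None,
    rng: np.random.Generator | None = None,
    sample_rate: float = DEFAULT_FS,
    rove: RoveSpec | None = None,
) -> Waveform:
    """Sum of the target HCT, TMR-attenuated masker complex(es), and TEN.

    GEOM maskers use the broader 4–12 × F0 bandpass (filtered variant) or
    harmonics 5–11 (discrete variant); DBL maskers flank the target.  Level
    roving, when requested, is applied independently per complex.
    """
    rng = np.random.default_rng(rng)

    def _prep(spec: ToneSpec) -> Waveform:
        if rove is not None:
            spec = apply_rove(spec, rove, rng, rove_phases=False)
        return synth_tone(spec, sample_rate)

    out = _prep(target)
    if masker is not None and np.isfinite(masker.tmr):
        gain_db = -masker.tmr
        levels = target.levels_array() + gain_db
        for mf0 in masker.masker_f0s:
            if masker.masker_kind == "GEOM" and target.kind == "hct_discrete":
                harm = tuple(range(min(target.harmonics) - 1, max(target.harmonics) + 2))
            else:
                harm = target.harmonics
            mspec = target.replace(
                f_or_f0=mf0,
                harmonics=harm,
                component_levels=(float(levels[0]),),
                filter_cutoffs=masker.filter_cutoffs
                if target.kind == "hct_filtered"
                else target.filter_cutoffs,
            )
            out = out + _prep(mspec)
    if noise is not None:
        out = out + synth_ten(noise, target.duration, sample_rate, rng)
    return out
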