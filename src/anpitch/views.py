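"""Excitation-pattern and autocorrelogram population views.

Excitation patterns summarize the rate-place code: the time-averaged
firing rate versus CF over a 200-channel grid spanning 4–12 × F0, averaged
over repeated syntheses with fresh level roving and fresh
threshold-equalizing noise.  Autocorrelograms summarize temporal coding:
the normalized autocorrelation of each channel's instantaneous rate over
lag, with the summary autocorrelation function (sACF) formed by summing
the autocorrelogram along the CF axis; periodicity at the target F0 shows
up as sACF peaks at integer multiples of the target period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frontend import PopulationSpec
from .stimuli import Waveform

__all__ = [
    "ExcitationPattern",
    "Autocorrelogram",
    "excitation_pattern",
    "autocorrelogram",
    "temporal_cue_salience",
    "excitation_cf_grid",
    "acg_cf_grid",
]


def excitation_cf_grid(f0: float, n_cf: int = 200) -> np.ndarray:
    """200 log-spaced CFs spanning 4–12 × F0 (excitation patterns)."""
    return np.geomspace(4.0 * f0, 12.0 * f0, n_cf)


def acg_cf_grid(f0: float, n_cf: int = 100) -> np.ndarray:
    """Linearly spaced CFs spanning 4–12 × F0 (autocorrelograms)."""
    return np.linspace(4.0 * f0, 12.0 * f0, n_cf)


@dataclass
class ExcitationPattern:
    """Mean and SD (over repeats) of time-averaged rate versus CF."""

    cf_grid: np.ndarray
    mean_rate: np.ndarray
    sd_rate: np.ndarray
    fiber_class: str
    n_repeats: int


@dataclass
class Autocorrelogram:
    """Per-CF normalized rate autocorrelation over lag, plus the sACF."""

    cf_grid: np.ndarray
    lags: np.ndarray
    acf: np.ndarray
    sacf: np.ndarray


def excitation_pattern(
    stim_builder,
    frontend,
    population: PopulationSpec,
    n_repeats: int = 10,
    rng: np.random.Generator | None = None,
) -> ExcitationPattern:
    """Average-rate excitation pattern over fresh stimulus draws.

    ``stim_builder(rng)`` must return a :class:`Waveform` with a fresh
    sample of level roving and masking noise on each call.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(rng)
    means = np.empty((n_repeats, len(population.cf_grid)))
    for k in range(n_repeats):
        wave = stim_builder(rng)
        resp = frontend.simulate_rates(wave, population)
        means[k] = resp.time_averaged()
    return ExcitationPattern(
        cf_grid=population.cf_grid.copy(),
        mean_rate=means.mean(axis=0),
        sd_rate=means.std(axis=0, ddof=0),
        fiber_class=population.fiber_class,
        n_repeats=n_repeats,
    )


def _normalized_acf(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased, variance-normalized autocorrelation of a rate waveform.

    Mean-subtracted and scaled so acf(0) = 1; a constant waveform (zero
    variance) degenerates to the flat mean-normalized convention acf ≡ 1.
    """
    x = np.asarray(x, float)
    xc = x - x.mean()
    var = float(np.dot(xc, xc))
    if var <= 1e-12 * len(x) * max(x.mean() ** 2, 1e-30):
        return np.ones(n_lags)
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[:n_lags]
    return acov / var


def autocorrelogram(
    stim_or_builder,
    frontend,
    population: PopulationSpec,
    max_lag: float,
    rng: np.random.Generator | None = None,
) -> Autocorrelogram:
    """Per-CF normalized autocorrelation of the instantaneous rate over
    lags [0, max_lag], and the sACF (column sum over CFs)."""
    rng = np.random.default_rng(rng)
    wave = stim_or_builder(rng) if callable(stim_or_builder) else stim_or_builder
    if wave.duration < 2 * max_lag:
        raise ValueError("stimulus duration must be at least twice max_lag")
    resp = frontend.simulate_rates(wave, population)
    dt = 1.0 / wave.sample_rate
    n_lags = int(round(max_lag / dt)) + 1
    acf = np.empty((len(population.cf_grid), n_lags))
    for i, row in enumerate(resp.rates):
        acf[i] = _normalized_acf(row, n_lags)
    return Autocorrelogram(
        cf_grid=population.cf_grid.copy(),
        lags=np.arange(n_lags) * dt,
        acf=acf,
        sacf=acf.sum(axis=0),
    )


def temporal_cue_salience(acg: Autocorrelogram, target_period: float) -> float:
    """Scalar summary of the temporal F0 cue: the sACF at the target-period
    lag relative to the local median, (sACF(T) − median) / median, with the
    median taken over lags in [0.5, 1.5] × target period."""
    lags = acg.lags
    if target_period > lags[-1]:
        raise ValueError("target period outside the lag range")
    i_t = int(np.argmin(np.abs(lags - target_period)))
    window = (lags >= 0.5 * target_period) & (lags <= 1.5 * target_period)
    local = float(np.median(acg.sacf[window]))
    if local == 0:
        return float(acg.sacf[i_t])
    return float((acg.sacf[i_t] - local) / abs(local))
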