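"""Frequency- and F0-discrimination simulation protocols.

For each frequency (pure tones) or F0 (bandpass-filtered harmonic complex
tones) on a log-spaced grid, the pipeline synthesizes the stimulus at a
level fixed relative to the front end's rate-level threshold, simulates
the auditory-nerve population response, and converts the (expected) Fisher
information plus prior information into a Cramér–Rao JND for the
all-information and rate-place observers.  Threshold curves are smoothed
with LOESS on log-log coordinates, and high/low-frequency threshold ratios
are read off the smoothed curves.

Population conventions: FDL runs use 40 CFs log-spaced over 0.5–1.5 × f
with 72 fibers per CF (≈ 2880 ≈ 3000 high-spontaneous-rate fibers near the
tone); F0DL runs use 40 CFs over 5–11 × F0 with 51 fibers per CF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import stimuli
from .stimuli import ToneSpec, RoveSpec, synth_tone
from .frontend import (
    PopulationSpec,
    RateLevelThresholdMap,
    level_re_threshold,
)
from .observer import (
    Parameter,
    ParameterSpec,
    cached_rate_function,
    crlb_variance,
    expected_fisher,
    prior_info_matrix,
    rate_place_transform,
    threshold_from_variance,
)

__all__ = [
    "ExperimentGrid",
    "desk_grid",
    "full_grid",
    "run_fdl",
    "run_f0dl",
    "loess_log_interp",
    "threshold_ratio",
    "roving_effect",
]

OBSERVERS = ("all_information", "rate_place")


@dataclass(frozen=True)
class ExperimentGrid:
    """A discrimination-simulation grid.

    ``task`` is ``"FDL"`` (pure tones, CFs 0.5–1.5 × f, 72 fibers/CF) or
    ``"F0DL"`` (filtered HCTs, CFs 5–11 × F0, 51 fibers/CF).  ``levels``
    are dB re: the rate-level threshold (at the 8th harmonic for F0DL).
    ``roving`` is ``"none"``, ``"level"``, or ``"phase"``.
    """

    task: str
    frequencies: np.ndarray
    levels: tuple = (30.0,)
    roving: str = "none"
    n_cf: int = 40
    fibers_per_cf: int | None = None
    n_draws: int = 4
    sample_rate: float = 500_000.0
    duration: float = 0.1

    def __post_init__(self):
        if self.task not in ("FDL", "F0DL"):
            raise ValueError("task must be FDL or F0DL")
        if self.roving not in ("none", "level", "phase"):
            raise ValueError("roving must be none, level, or phase")
        freqs = np.atleast_1d(np.asarray(self.frequencies, float))
        if np.any(freqs <= 0) or np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be positive and sorted")
        object.__setattr__(self, "frequencies", freqs)
        if self.fibers_per_cf is None:
            object.__setattr__(self, "fibers_per_cf", 72 if self.task == "FDL" else 51)

    @property
    def cf_span(self) -> tuple:
        return (0.5, 1.5) if self.task == "FDL" else (5.0, 11.0)

    def population(self, nominal: float) -> PopulationSpec:
        lo, hi = self.cf_span
        return PopulationSpec(
            np.geomspace(lo * nominal, hi * nominal, self.n_cf),
            fibers_per_cf=self.fibers_per_cf,
        )

    def point_sample_rate(self, nominal: float) -> float:
        """Simulation rate for one grid point.

        Discrimination runs use a much higher rate (default 500 kHz) than
        the rest of the package: harmonics of the half-wave-rectified
        drive alias across the Nyquist frequency, and at lower rates the
        low-order folds land inside the phase-locking passband and
        contaminate the finite-difference Fisher integrands with
        phase-amplified artifacts.  At 500 kHz the folded harmonics are of
        high enough order to be negligible at the tested levels.
        """
        return self.sample_rate

    def target_step(self) -> float:
        """Finite-difference step for the target parameter, set so the
        phase excursion 2*pi*n_harm*step*T over the stimulus stays small
        (n_harm = 1 for pure tones, up to ~11 for the filtered HCT)."""
        return 0.25 if self.task == "FDL" else 0.025


def desk_grid(task: str, roving: str = "none", n_freqs: int = 9, **kwargs) -> ExperimentGrid:
    """Desk-scale preset: 9 log-spaced frequencies/F0s, one level (30 dB
    re: threshold), 4 rove draws."""
    span = (1400.0, 14_000.0) if task == "FDL" else (180.0, 1800.0)
    return ExperimentGrid(task, np.geomspace(*span, n_freqs), roving=roving, **kwargs)


def full_grid(task: str, roving: str = "none", **kwargs) -> ExperimentGrid:
    """Full preset: 24 frequencies/F0s at 20, 30, and 40 dB re: threshold."""
    span = (1400.0, 14_000.0) if task == "FDL" else (180.0, 1800.0)
    kwargs.setdefault("levels", (20.0, 30.0, 40.0))
    kwargs.setdefault("n_draws", 8)
    return ExperimentGrid(task, np.geomspace(*span, 24), roving=roving, **kwargs)


# ---------------------------------------------------------------------------
# parameter specs and rate functions


def _fdl_pspec(
    freq: float, level_db: float, roving: str, rove: RoveSpec, step: float = 0.25
) -> ParameterSpec:
    params = [Parameter("frequency", freq, role="target", step=step)]
    if roving == "level":
        params.append(
            Parameter(
                "level",
                level_db,
                role="roved",
                rove_halfwidth=rove.level_halfwidth,
                prior_sd=rove.eval_level_sd,
            )
        )
    elif roving == "phase":
        params.append(
            Parameter(
                "phase",
                0.0,
                role="roved",
                rove_halfwidth=np.deg2rad(rove.phase_range) / 2.0,
                prior_sd=np.deg2rad(rove.eval_phase_sd),
            )
        )
    return ParameterSpec(tuple(params))


def _fdl_rate_fn(grid: ExperimentGrid, frontend, freq: float, level_db: float, roving: str):
    pop = grid.population(freq)
    fs = grid.point_sample_rate(freq)

    def rate_fn(theta: np.ndarray):
        level = theta[1] if roving == "level" else level_db
        phase = theta[1] if roving == "phase" else 0.0
        spec = ToneSpec(
            kind="pure",
            f_or_f0=float(theta[0]),
            component_levels=(float(level),),
            component_phases=(float(phase),),
            duration=grid.duration,
        )
        return frontend.simulate_rates(synth_tone(spec, fs), pop)

    return cached_rate_function(rate_fn)


def _f0dl_nuisance_harmonics(f0: float, sample_rate: float) -> tuple:
    """Components treated as nuisance parameters when roving: those within
    40 dB of the passband maximum after the bandpass filter."""
    hs = stimuli.filtered_hct_harmonics(f0, sample_rate, max_attenuation_db=40.0)
    return tuple(int(h) for h in hs)


def _f0dl_pspec(
    f0: float, level_db: float, harmonics: tuple, roving: str, rove: RoveSpec,
    step: float = 0.025,
) -> ParameterSpec:
    params = [Parameter("f0", f0, role="target", step=step)]
    if roving == "level":
        for h in harmonics:
            params.append(
                Parameter(
                    f"level_h{h}",
                    level_db,
                    role="roved",
                    rove_halfwidth=rove.level_halfwidth,
                    prior_sd=rove.eval_level_sd,
                )
            )
    elif roving == "phase":
        for h in harmonics:
            params.append(
                Parameter(
                    f"phase_h{h}",
                    0.0,
                    role="roved",
                    rove_halfwidth=np.deg2rad(rove.phase_range) / 2.0,
                    prior_sd=np.deg2rad(rove.eval_phase_sd),
                )
            )
    return ParameterSpec(tuple(params))


def _f0dl_rate_fn(
    grid: ExperimentGrid,
    frontend,
    f0_nominal: float,
    level_db: float,
    harmonics: tuple,
    roving: str,
):
    pop = grid.population(f0_nominal)
    fs = grid.point_sample_rate(f0_nominal)
    retained = stimuli.filtered_hct_harmonics(f0_nominal, fs, max_attenuation_db=100.0)

    def rate_fn(theta: np.ndarray):
        levels = np.full(len(harmonics), level_db)
        phases = np.zeros(len(harmonics))
        if roving == "level":
            levels = np.asarray(theta[1:], float)
        elif roving == "phase":
            phases = np.asarray(theta[1:], float)
        spec = ToneSpec(
            kind="hct_filtered",
            f_or_f0=float(theta[0]),
            harmonics=harmonics,
            component_levels=tuple(levels),
            component_phases=tuple(phases),
            duration=grid.duration,
        )
        # the bandpass filter stays anchored to the nominal F0, as in the
        # behavioral stimulus (reference and target share one filter)
        wave = stimuli.synth_filtered_hct(
            spec, fs, f0_filter=f0_nominal, retained_harmonics=retained
        )
        return frontend.simulate_rates(wave, pop)

    return cached_rate_function(rate_fn)


# ---------------------------------------------------------------------------
# runners


def _point_thresholds(
    rate_fn,
    pspec: ParameterSpec,
    grid: ExperimentGrid,
    observers: tuple,
    rng: np.random.Generator,
) -> dict:
    free = pspec.free_indices()
    target_pos = int(np.nonzero(free == pspec.target_index)[0][0])
    prior = prior_info_matrix(pspec)
    point_seed = int(rng.integers(2**31))
    out = {}
    for observer in observers:
        if observer == "rate_place":
            fn = lambda th: rate_place_transform(rate_fn(th))  # noqa: E731
        else:
            fn = rate_fn
        # same sub-seed for both observers so they see identical rove draws
        ei = expected_fisher(fn, pspec, n_draws=grid.n_draws, rng=np.random.default_rng(point_seed))
        var = crlb_variance(ei, prior, target_pos)
        out[observer] = threshold_from_variance(var, observer=observer)
    return out


def run_fdl(
    grid: ExperimentGrid,
    frontend,
    thr_map: RateLevelThresholdMap,
    observers: tuple = OBSERVERS,
    rove: RoveSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated pure-tone frequency difference limens over the grid.

    Returns a tidy frame with one row per (frequency, level, observer):
    ``jnd_hz`` and ``jnd_pct`` (Weber fraction × 100).
    """
    if grid.task != "FDL":
        raise ValueError("grid.task must be FDL")
    rove = rove or RoveSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for level_re in grid.levels:
        for freq in grid.frequencies:
            level_db = level_re_threshold(freq, level_re, thr_map)
            pspec = _fdl_pspec(freq, level_db, grid.roving, rove, grid.target_step())
            rate_fn = _fdl_rate_fn(grid, frontend, freq, level_db, grid.roving)
            ests = _point_thresholds(rate_fn, pspec, grid, observers, rng)
            for observer, est in ests.items():
                rows.append(
                    dict(
                        task="FDL",
                        frequency=freq,
                        level_db_re_thr=level_re,
                        level_db_spl=level_db,
                        observer=observer,
                        roving=grid.roving,
                        jnd_hz=est.jnd,
                        jnd_pct=100.0 * est.jnd / freq,
                        seed=seed,
                    )
                )
    return pd.DataFrame(rows)


def run_f0dl(
    grid: ExperimentGrid,
    frontend,
    thr_map: RateLevelThresholdMap,
    observers: tuple = OBSERVERS,
    rove: RoveSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated F0 difference limens for the bandpass-filtered HCT
    (all harmonics to Nyquist, zero-phase Butterworth 5.5–10.5 × F0,
    100 ms, no noise, sine phase unless roved); per-component level is
    set relative to the rate-level threshold at the 8th harmonic."""
    if grid.task != "F0DL":
        raise ValueError("grid.task must be F0DL")
    rove = rove or RoveSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for level_re in grid.levels:
        for f0 in grid.frequencies:
            level_db = level_re_threshold(8.0 * f0, level_re, thr_map)
            harmonics = _f0dl_nuisance_harmonics(f0, grid.point_sample_rate(f0))
            pspec = _f0dl_pspec(f0, level_db, harmonics, grid.roving, rove, grid.target_step())
            rate_fn = _f0dl_rate_fn(grid, frontend, f0, level_db, harmonics, grid.roving)
            ests = _point_thresholds(rate_fn, pspec, grid, observers, rng)
            for observer, est in ests.items():
                rows.append(
                    dict(
                        task="F0DL",
                        frequency=f0,
                        level_db_re_thr=level_re,
                        level_db_spl=level_db,
                        observer=observer,
                        roving=grid.roving,
                        jnd_hz=est.jnd,
                        jnd_pct=100.0 * est.jnd / f0,
                        seed=seed,
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# smoothing and summaries


def loess_log_interp(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    frac: float = 0.5,
) -> np.ndarray:
    """LOESS fit of log(y) versus log(x), evaluated at ``x_eval``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x_eval = np.atleast_1d(np.asarray(x_eval, float))
    if np.any(x_eval < x.min() - 1e-9) or np.any(x_eval > x.max() + 1e-9):
        raise ValueError("LOESS evaluation outside the grid span (no extrapolation)")
    order = np.argsort(x_eval)
    fit = lowess(np.log(y), np.log(x), frac=frac, it=0, xvals=np.log(x_eval[order]))
    out = np.empty_like(fit)
    out[order] = fit
    return np.exp(out)


def threshold_ratio(
    curve: pd.DataFrame,
    f_hi: float,
    f_lo: float,
    observer: str = "all_information",
    level_db_re_thr: float = 30.0,
    frac: float = 0.5,
) -> float:
    """Ratio of LOESS-interpolated relative JNDs (Δf/f) at ``f_hi`` versus
    ``f_lo`` for one observer and level."""
    sub = curve[
        (curve["observer"] == observer) & (curve["level_db_re_thr"] == level_db_re_thr)
    ].sort_values("frequency")
    if len(sub) < 3:
        raise ValueError("not enough grid points for interpolation")
    vals = loess_log_interp(
        sub["frequency"].to_numpy(), sub["jnd_pct"].to_numpy(), np.array([f_hi, f_lo]), frac
    )
    return float(vals[0] / vals[1])


def roving_effect(curve_roved: pd.DataFrame, curve_fixed: pd.DataFrame) -> pd.DataFrame:
    """Element-wise roved/fixed JND ratio per (frequency, level, observer)."""
    keys = ["task", "frequency", "level_db_re_thr", "observer"]
    merged = curve_roved.merge(curve_fixed, on=keys, suffixes=("_roved", "_fixed"))
    if len(merged) != len(curve_roved):
        raise ValueError("grids do not match")
    merged["jnd_ratio"] = merged["jnd_hz_roved"] / merged["jnd_hz_fixed"]
    return merged[keys + ["jnd_ratio"]]
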