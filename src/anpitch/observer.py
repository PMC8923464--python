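"""Fisher-information / Cramér–Rao ideal-observer machinery.

Spike trains of each model fiber are taken to be inhomogeneous Poisson
with intensity r_i(t, θ) and conditionally independent across fibers.  The
Fisher information about the stimulus parameter vector θ is then

    I(θ)[α, β] = Σ_i K_i ∫ (1/r_i) (∂r_i/∂θ_α)(∂r_i/∂θ_β) dt,

with K_i the fibers-per-CF multiplier.  Roved (nuisance) parameters enter
twice: the expected information E_θ[I(θ)] is a Monte-Carlo mean over their
*synthesis* (uniform) distributions, while a diagonal prior-information
matrix A(θ) with entries 1/ν² encodes the normal approximation to those
distributions.  The variance bound of the target parameter is element
(target, target) of (E[I] + A)^{-1}, and the just-noticeable difference at
the 70.7%-correct point is its square root.

The "all-information" observer uses the full spatiotemporal rate pattern;
the "rate-place" observer first replaces each fiber's rate by its time
average.  A Monte-Carlo maximum-likelihood classifier over sampled spike
trains serves as an independent check that the bound sits near the
70.7%-correct point in the one-parameter case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frontend import RateResponse

__all__ = [
    "Parameter",
    "ParameterSpec",
    "prior_info_matrix",
    "fisher_matrix",
    "expected_fisher",
    "crlb_variance",
    "threshold_from_variance",
    "ThresholdEstimate",
    "rate_place_transform",
    "draw_spike_times",
    "oracle_ml_discrimination",
    "cached_rate_function",
]


@dataclass(frozen=True)
class Parameter:
    """One stimulus parameter of the discrimination task.

    role : ``"target"`` (the discriminated parameter), ``"fixed"`` (known
        constant), or ``"roved"`` (random nuisance parameter).
    step : central finite-difference step in the parameter's own units.
    rove_halfwidth : halfwidth of the uniform synthesis distribution
        (roved parameters only).
    prior_sd : SD ν of the normal approximation used for the prior
        information 1/ν² (roved parameters only).
    """

    name: str
    value: float
    role: str = "fixed"
    step: float | None = None
    rove_halfwidth: float = 0.0
    prior_sd: float | None = None

    def __post_init__(self):
        if self.role not in ("target", "fixed", "roved"):
            raise ValueError(f"unknown parameter role {self.role!r}")
        if self.role == "roved" and (self.prior_sd is None or self.prior_sd <= 0):
            raise ValueError("roved parameters need a positive prior_sd")
        if self.step is not None and self.step <= 0:
            raise ValueError("finite-difference steps must be positive")


@dataclass(frozen=True)
class ParameterSpec:
    """The parameter vector θ = (θ_1 … θ_n) with exactly one target."""

    parameters: tuple

    def __post_init__(self):
        params = tuple(self.parameters)
        if sum(p.role == "target" for p in params) != 1:
            raise ValueError("exactly one target parameter required")
        object.__setattr__(self, "parameters", params)

    @property
    def n(self) -> int:
        return len(self.parameters)

    @property
    def target_index(self) -> int:
        return next(i for i, p in enumerate(self.parameters) if p.role == "target")

    @property
    def names(self) -> tuple:
        return tuple(p.name for p in self.parameters)

    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters], dtype=float)

    def steps(self) -> np.ndarray:
        out = np.empty(self.n)
        for i, p in enumerate(self.parameters):
            if p.step is not None:
                out[i] = p.step
            else:
                out[i] = default_step(p)
        return out

    def free_indices(self) -> np.ndarray:
        """Parameters entering the Fisher matrix (target + roved)."""
        return np.array(
            [i for i, p in enumerate(self.parameters) if p.role in ("target", "roved")]
        )


def default_step(p: Parameter) -> float:
    """Default central-difference step: relative 1e-3 for frequency-like
    parameters, 0.25 dB for levels, 1 degree for phases."""
    name = p.name.lower()
    if "level" in name:
        return 0.25
    if "phase" in name:
        return np.deg2rad(1.0)
    return max(abs(p.value) * 1e-3, 1e-9)


def prior_info_matrix(pspec: ParameterSpec) -> np.ndarray:
    """Diagonal prior-information matrix A(θ): 1/ν² for roved parameters,
    0 for the target and fixed parameters."""
    free = pspec.free_indices()
    a = np.zeros((len(free), len(free)))
    for k, i in enumerate(free):
        p = pspec.parameters[i]
        if p.role == "roved":
            a[k, k] = 1.0 / p.prior_sd**2
    return a


def cached_rate_function(rate_fn):
    """Memoize a θ → RateResponse map on the (rounded) parameter tuple."""
    cache: dict = {}

    def wrapped(theta: np.ndarray) -> RateResponse:
        key = tuple(np.round(np.asarray(theta, float), 12))
        if key not in cache:
            cache[key] = rate_fn(np.asarray(theta, float))
        return cache[key]

    wrapped.cache = cache
    return wrapped


def fisher_matrix(
    rate_fn,
    pspec: ParameterSpec,
    theta0: np.ndarray | None = None,
) -> np.ndarray:
    """Fisher information matrix at θ0 over the free (target + roved)
    parameters, by central finite differences and trapezoidal integration.

    ``rate_fn`` maps a full parameter vector to a :class:`RateResponse`.
    """
    theta0 = pspec.values() if theta0 is None else np.asarray(theta0, float)
    free = pspec.free_indices()
    steps = pspec.steps()
    base = rate_fn(theta0)
    r0 = np.asarray(base.rates, float)
    if np.any(r0 <= 0):
        raise ValueError("rates must be strictly positive for Fisher integration")
    dt = float(base.time[1] - base.time[0])
    k_mult = base.fibers_per_cf

    derivs = []
    for i in free:
        h = steps[i]
        up = theta0.copy()
        dn = theta0.copy()
        up[i] += h
        dn[i] -= h
        derivs.append((np.asarray(rate_fn(up).rates, float) - np.asarray(rate_fn(dn).rates, float)) / (2 * h))

    m = len(free)
    info = np.empty((m, m))
    inv_r = 1.0 / r0
    for a in range(m):
        for b in range(a, m):
            integrand = inv_r * derivs[a] * derivs[b]
            val = k_mult * np.trapezoid(integrand, dx=dt, axis=1).sum()
            info[a, b] = info[b, a] = val
    return info


def expected_fisher(
    rate_fn,
    pspec: ParameterSpec,
    n_draws: int = 8,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean Fisher matrix over ``n_draws`` samples of the roved parameters
    from their uniform synthesis distributions (target held at nominal)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng)
    roved = [i for i, p in enumerate(pspec.parameters) if p.role == "roved"]
    theta0 = pspec.values()
    if not roved:
        return fisher_matrix(rate_fn, pspec, theta0)
    acc = None
    for _ in range(n_draws):
        theta = theta0.copy()
        for i in roved:
            p = pspec.parameters[i]
            theta[i] = p.value + rng.uniform(-p.rove_halfwidth, p.rove_halfwidth)
        mat = fisher_matrix(rate_fn, pspec, theta)
        acc = mat if acc is None else acc + mat
    return acc / n_draws


def crlb_variance(
    expected_info: np.ndarray,
    prior_info: np.ndarray,
    target_index: int = 0,
) -> float:
    """Cramér–Rao variance bound of the target parameter:
    element (target, target) of (E[I] + A)^{-1}."""
    total = np.asarray(expected_info, float) + np.asarray(prior_info, float)
    try:
        cov = np.linalg.inv(total)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular information matrix: non-identifiable configuration") from exc
    var = float(cov[target_index, target_index])
    if var <= 0:
        raise ValueError("non-positive variance bound: information matrix not PD")
    return var


@dataclass(frozen=True)
class ThresholdEstimate:
    """A JND (70.7%-correct threshold) with its variance bound."""

    observer: str
    variance_bound: float
    jnd: float
    baseline: float | None = None

    @property
    def jnd_percent(self) -> float | None:
        if self.baseline is None:
            return None
        return 100.0 * self.jnd / self.baseline


def threshold_from_variance(
    variance: float,
    observer: str = "all_information",
    baseline: float | None = None,
) -> ThresholdEstimate:
    """JND = sqrt(variance bound); optionally expressed as % of baseline."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    return ThresholdEstimate(
        observer=observer,
        variance_bound=float(variance),
        jnd=float(np.sqrt(variance)),
        baseline=baseline,
    )


def rate_place_transform(resp: RateResponse) -> RateResponse:
    """Replace each fiber's rate by its time average, held constant over
    the duration (the rate-place observer's representation)."""
    means = resp.rates.mean(axis=1, keepdims=True)
    return RateResponse(
        rates=np.broadcast_to(means, resp.rates.shape).copy(),
        time=resp.time,
        cf_grid=resp.cf_grid,
        fibers_per_cf=resp.fibers_per_cf,
        stimulus_params=dict(resp.stimulus_params),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo maximum-likelihood oracle


def draw_spike_times(resp: RateResponse, rng: np.random.Generator | None = None) -> list:
    """Sample spike times per simulated fiber channel by thinning a
    homogeneous Poisson process at the channel's peak rate."""
    rng = np.random.default_rng(rng)
    dt = float(resp.time[1] - resp.time[0])
    duration = len(resp.time) * dt
    trains = []
    for row in resp.rates:
        r_max = float(row.max())
        n_cand = rng.poisson(r_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        idx = np.minimum((cand / dt).astype(int), len(row) - 1)
        keep = rng.uniform(0.0, 1.0, size=n_cand) < row[idx] / r_max
        trains.append(cand[keep])
    return trains


def oracle_ml_discrimination(
    rate_fn,
    pspec: ParameterSpec,
    delta: float,
    n_trials: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Proportion correct of an exact-template maximum-likelihood observer
    in a two-interval forced choice between θ0 and θ0 + Δ (one-parameter
    case).

    Each trial draws one spike-train observation from the baseline
    intensity and one from the incremented intensity; the observer
    attributes the increment to the interval with the larger Poisson
    log-likelihood ratio.  Spike counts are drawn per time bin from the
    discretized inhomogeneous Poisson law (bin counts are a sufficient
    statistic for the likelihood ratio with piecewise-constant intensity).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if any(p.role == "roved" for p in pspec.parameters):
        raise ValueError("oracle supports the one-parameter (no-rove) case only")
    rng = np.random.default_rng(rng)
    theta0 = pspec.values()
    theta1 = theta0.copy()
    theta1[pspec.target_index] += delta
    resp0, resp1 = rate_fn(theta0), rate_fn(theta1)
    dt = float(resp0.time[1] - resp0.time[0])
    k_mult = resp0.fibers_per_cf
    lam0 = (resp0.rates * dt * k_mult).ravel()
    lam1 = (resp1.rates * dt * k_mult).ravel()
    w = np.log(lam1 / lam0)
    const = (lam1 - lam0).sum()

    def llr_batch(lam: np.ndarray, n: int) -> np.ndarray:
        counts = rng.poisson(lam[None, :], size=(n, len(lam)))
        return counts @ w - const

    n_correct = 0.0
    batch = 250
    done = 0
    while done < n_trials:
        n = min(batch, n_trials - done)
        llr_base = llr_batch(lam0, n)
        llr_incr = llr_batch(lam1, n)
        n_correct += float((llr_incr > llr_base).sum())
        n_correct += 0.5 * float((llr_incr == llr_base).sum())
        done += n
    return n_correct / n_trials
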