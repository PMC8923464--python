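"""Fisher/CRLB machinery against closed forms and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anpitch.frontend import RateResponse
from anpitch.observer import (
    Parameter,
    ParameterSpec,
    cached_rate_function,
    crlb_variance,
    draw_spike_times,
    expected_fisher,
    fisher_matrix,
    oracle_ml_discrimination,
    prior_info_matrix,
    rate_place_transform,
    threshold_from_variance,
)

FS = 50_000.0
T = 0.1
N = int(T * FS)
TIME = np.arange(N) / FS


def _resp(rates, k=1):
    rates = np.atleast_2d(rates)
    return RateResponse(rates, TIME, np.arange(rates.shape[0]) + 1.0, fibers_per_cf=k)


def constant_rate_fn(theta):
    """One fiber with constant rate equal to theta (spikes/s)."""
    return _resp(np.full(N, float(theta[0])))


class TestFisherMatrix:
    def test_constant_rate_closed_form(self):
        """I = T / r for a single fiber whose constant rate is the
        parameter itself."""
        pspec = ParameterSpec((Parameter("rate", 100.0, role="target", step=1e-3),))
        info = fisher_matrix(constant_rate_fn, pspec)
        # dt*(n-1) trapezoid window vs the nominal duration
        t_window = TIME[-1]
        assert info[0, 0] == pytest.approx(t_window / 100.0, rel=1e-9)

    def test_insensitive_parameter_gives_zero_row(self):
        def rate_fn(theta):
            return _resp(np.full(N, float(theta[0])))

        pspec = ParameterSpec(
            (
                Parameter("rate", 100.0, role="target", step=1e-3),
                Parameter("dummy", 5.0, role="roved", prior_sd=1.0, step=1e-3),
            )
        )
        info = fisher_matrix(rate_fn, pspec)
        assert info[1, 1] == 0.0
        assert info[0, 1] == 0.0

    def test_sinusoidal_rate_matches_analytic_oracle(self):
        """Finite-difference Fisher information about the modulation
        frequency agrees within 1% with quadrature using the analytic
        derivative of r(t) = R0 (1 + m cos(2 pi F t))."""
        r0, m = 120.0, 0.4

        def rate_fn(theta):
            return _resp(r0 * (1 + m * np.cos(2 * np.pi * theta[0] * TIME)))

        pspec = ParameterSpec((Parameter("mod_freq", 50.0, role="target"),))
        info = fisher_matrix(rate_fn, pspec)
        rates = r0 * (1 + m * np.cos(2 * np.pi * 50.0 * TIME))
        drate = -r0 * m * 2 * np.pi * TIME * np.sin(2 * np.pi * 50.0 * TIME)
        oracle = np.trapezoid(drate**2 / rates, TIME)
        assert info[0, 0] == pytest.approx(oracle, rel=0.01)

    def test_fiber_multiplier_scales_information(self):
        def rate_fn_k(theta):
            return _resp(np.full(N, float(theta[0])), k=7)

        pspec = ParameterSpec((Parameter("rate", 100.0, role="target", step=1e-3),))
        info1 = fisher_matrix(constant_rate_fn, pspec)
        info7 = fisher_matrix(rate_fn_k, pspec)
        assert info7[0, 0] == pytest.approx(7 * info1[0, 0], rel=1e-12)

    def test_nonpositive_rate_rejected(self):
        def rate_fn(theta):
            return _resp(np.zeros(N))

        pspec = ParameterSpec((Parameter("x", 1.0, role="target", step=1e-3),))
        with pytest.raises(ValueError, match="positive"):
            fisher_matrix(rate_fn, pspec)

    def test_symmetry_and_psd(self):
        """Fisher matrices are symmetric positive semidefinite."""

        def rate_fn(theta):
            return _resp(
                100.0
                + theta[0] * np.cos(2 * np.pi * 40 * TIME)
                + theta[1] * np.sin(2 * np.pi * 40 * TIME)
                + 0.5 * theta[0] * theta[1]
            )

        pspec = ParameterSpec(
            (
                Parameter("a", 20.0, role="target", step=1e-3),
                Parameter("b", 10.0, role="roved", prior_sd=5.0, step=1e-3),
            )
        )
        info = fisher_matrix(rate_fn, pspec)
        np.testing.assert_allclose(info, info.T)
        assert np.min(np.linalg.eigvalsh(info)) >= -1e-10 * np.trace(info)


class TestExpectedFisher:
    def test_all_fixed_equals_plain_fisher(self):
        pspec = ParameterSpec((Parameter("rate", 100.0, role="target", step=1e-3),))
        ei = expected_fisher(constant_rate_fn, pspec, n_draws=5, rng=np.random.default_rng(0))
        info = fisher_matrix(constant_rate_fn, pspec)
        np.testing.assert_array_equal(ei, info)

    def test_linear_model_converges_to_analytic_average(self):
        """For information linear in the roved parameter, the Monte-Carlo
        expectation approaches the analytic average over the uniform
        synthesis distribution."""

        def rate_fn(theta):
            # I_{00} = T * theta1 / 100^2-ish: rate constant in time,
            # derivative w.r.t. target scaled by sqrt(theta1)
            base = np.full(N, 100.0)
            return _resp(base + theta[0] * np.sqrt(max(theta[1], 0.0)) * np.ones(N))

        pspec = ParameterSpec(
            (
                Parameter("a", 0.0, role="target", step=1e-4),
                Parameter("b", 4.0, role="roved", rove_halfwidth=3.0, prior_sd=2.0, step=1e-4),
            )
        )
        ei = expected_fisher(rate_fn, pspec, n_draws=512, rng=np.random.default_rng(1))
        # I_00(b) = T * b / 100; E[b] = 4 over U(1, 7)
        t_window = TIME[-1]
        assert ei[0, 0] == pytest.approx(t_window * 4.0 / 100.0, rel=0.05)

    def test_single_seeded_draw_reproducible(self):
        def rate_fn(theta):
            return _resp(np.full(N, 100.0 + theta[0] + theta[1] ** 2))

        pspec = ParameterSpec(
            (
                Parameter("a", 0.0, role="target", step=1e-3),
                Parameter("b", 2.0, role="roved", rove_halfwidth=1.0, prior_sd=2.0, step=1e-3),
            )
        )
        e1 = expected_fisher(rate_fn, pspec, n_draws=1, rng=np.random.default_rng(9))
        e2 = expected_fisher(rate_fn, pspec, n_draws=1, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(e1, e2)


def _cofactor_inverse_3x3(m):
    """Brute-force 3x3 inversion via the adjugate (independent of
    numpy.linalg)."""
    det = (
        m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
        - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
        + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
    )
    adj = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            minor = np.delete(np.delete(m, i, axis=0), j, axis=1)
            adj[j, i] = (-1) ** (i + j) * (minor[0, 0] * minor[1, 1] - minor[0, 1] * minor[1, 0])
    return adj / det


class TestCrlb:
    def test_scalar_no_prior(self):
        assert crlb_variance(np.array([[4.0]]), np.array([[0.0]]), 0) == pytest.approx(0.25)

    def test_two_dim_zero_cross_reduces_to_scalar(self):
        ei = np.array([[5.0, 0.0], [0.0, 3.0]])
        a = np.diag([0.0, 0.5])
        assert crlb_variance(ei, a, 0) == pytest.approx(1 / 5.0)

    def test_two_dim_matches_explicit_expression(self):
        """The 2x2 bound equals the explicit scalar-minus-penalty form:
        var = 1 / (I11 - I12^2 / (I22 + 1/nu^2))."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            b = rng.normal(size=(2, 2))
            ei = b @ b.T + 1e-3 * np.eye(2)
            nu2 = rng.uniform(0.1, 10.0)
            a = np.diag([0.0, 1.0 / nu2])
            explicit = 1.0 / (ei[0, 0] - ei[0, 1] ** 2 / (ei[1, 1] + 1.0 / nu2))
            assert crlb_variance(ei, a, 0) == pytest.approx(explicit, rel=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_random_spd_matches_cofactor_inversion(self, seed):
        rng = np.random.default_rng(seed)
        b = rng.normal(size=(3, 3))
        ei = b @ b.T + 0.1 * np.eye(3)
        a = np.diag(rng.uniform(0.0, 2.0, size=3))
        inv = _cofactor_inverse_3x3(ei + a)
        for k in range(3):
            assert crlb_variance(ei, a, k) == pytest.approx(inv[k, k], rel=1e-9)

    def test_singular_matrix_signaled(self):
        with pytest.raises(ValueError, match="singular|non-identifiable"):
            crlb_variance(np.zeros((2, 2)), np.zeros((2, 2)), 0)

    def test_nuisance_penalty_never_helps(self):
        """Adding a roved parameter with nonzero cross-sensitivity never
        decreases the target variance."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            b = rng.normal(size=(2, 2))
            ei = b @ b.T + 1e-3 * np.eye(2)
            nu2 = rng.uniform(0.01, 100.0)
            a = np.diag([0.0, 1.0 / nu2])
            var_with = crlb_variance(ei, a, 0)
            var_fixed = 1.0 / ei[0, 0]
            assert var_with >= var_fixed - 1e-15

    def test_prior_limit_recovers_fixed_parameter_bound(self):
        """As nu^2 -> 0 the bound converges to the fixed-parameter bound
        even with strong cross-sensitivity."""
        ei = np.array([[4.0, 3.0], [3.0, 9.0]])
        var_fixed = 1.0 / ei[0, 0]
        prev = np.inf
        for nu2 in [1.0, 1e-2, 1e-4, 1e-6]:
            var = crlb_variance(ei, np.diag([0.0, 1.0 / nu2]), 0)
            assert var <= prev + 1e-15
            prev = var
        assert prev == pytest.approx(var_fixed, rel=1e-4)


class TestThreshold:
    @pytest.mark.parametrize("variance,expected", [(4.0, 2.0), (0.25, 0.5)])
    def test_sqrt(self, variance, expected):
        assert threshold_from_variance(variance).jnd == expected

    def test_percent_of_baseline(self):
        est = threshold_from_variance(2.8**2, baseline=280.0)
        assert est.jnd_percent == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            threshold_from_variance(0.0)


class TestRatePlace:
    def test_constant_rate_identity(self):
        resp = _resp(np.full(N, 75.0))
        out = rate_place_transform(resp)
        np.testing.assert_array_equal(out.rates, resp.rates)

    def test_modulated_rate_becomes_mean(self):
        rate = 100.0 + 30.0 * np.sin(2 * np.pi * 100 * TIME)
        out = rate_place_transform(_resp(rate))
        np.testing.assert_allclose(out.rates, rate.mean())

    def test_data_processing_inequality(self):
        """Time-averaging never increases Fisher information: the
        rate-place diagonal is bounded by the all-information diagonal for
        randomized smooth rate families."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            base = 80.0 + 40.0 * rng.random(N)
            mod = rng.normal(size=N)
            # smooth the derivative profile
            kern = np.ones(200) / 200
            mod = np.convolve(mod, kern, mode="same")

            def rate_fn(theta, base=base, mod=mod):
                return _resp(base + theta[0] * mod)

            pspec = ParameterSpec((Parameter("x", 1.0, role="target", step=1e-4),))
            ai = fisher_matrix(rate_fn, pspec)[0, 0]
            rp = fisher_matrix(lambda th: rate_place_transform(rate_fn(th)), pspec)[0, 0]
            assert rp <= ai * (1 + 1e-9)


class TestSpikeSampling:
    def test_spike_times_sorted_within_duration(self):
        rate = 100.0 * (1 + 0.8 * np.sin(2 * np.pi * 50 * TIME))
        trains = draw_spike_times(_resp(rate), np.random.default_rng(2))
        for times in trains:
            assert np.all(np.diff(times) >= 0)
            if len(times):
                assert times[0] >= 0.0 and times[-1] <= T

    def test_spike_count_matches_intensity(self):
        rate = np.full(N, 200.0)
        rng = np.random.default_rng(3)
        counts = [len(draw_spike_times(_resp(rate), rng)[0]) for _ in range(200)]
        # mean count ~ Poisson(200 * 0.1) = 20
        assert np.mean(counts) == pytest.approx(20.0, rel=0.1)


class TestMlOracle:
    def test_zero_delta_is_chance(self):
        pspec = ParameterSpec((Parameter("rate", 100.0, role="target", step=1e-3),))
        pc = oracle_ml_discrimination(
            constant_rate_fn, pspec, 0.0, n_trials=500, rng=np.random.default_rng(0)
        )
        assert pc == pytest.approx(0.5, abs=0.07)

    def test_large_delta_is_perfect(self):
        pspec = ParameterSpec((Parameter("rate", 100.0, role="target", step=1e-3),))
        pc = oracle_ml_discrimination(
            constant_rate_fn, pspec, 200.0, n_trials=300, rng=np.random.default_rng(1)
        )
        assert pc > 0.97

    def test_roved_parameters_rejected(self):
        pspec = ParameterSpec(
            (
                Parameter("rate", 100.0, role="target", step=1e-3),
                Parameter("b", 0.0, role="roved", prior_sd=1.0),
            )
        )
        with pytest.raises(ValueError, match="one-parameter"):
            oracle_ml_discrimination(lambda th: constant_rate_fn(th), pspec, 1.0)


class TestStepRobustness:
    def test_halving_steps_changes_jnd_under_2pct(self, front, thr_map):
        """Central-difference convergence on the reference configuration."""
        from anpitch import experiments as ex

        grid = ex.ExperimentGrid("FDL", np.array([1800.0, 2000.0, 2200.0]))
        freq = 2000.0
        level = thr_map(freq) + 30.0
        rate_fn = ex._fdl_rate_fn(grid, front, freq, float(level), "none")
        jnds = []
        for step in [0.5, 0.25]:
            pspec = ParameterSpec((Parameter("frequency", freq, role="target", step=step),))
            info = fisher_matrix(rate_fn, pspec)
            jnds.append(np.sqrt(crlb_variance(info, np.zeros((1, 1)), 0)))
        assert abs(jnds[1] / jnds[0] - 1) < 0.02


class TestParameterSpec:
    def test_exactly_one_target_required(self):
        with pytest.raises(ValueError):
            ParameterSpec((Parameter("a", 1.0, role="fixed"),))
        with pytest.raises(ValueError):
            ParameterSpec(
                (Parameter("a", 1.0, role="target"), Parameter("b", 2.0, role="target"))
            )

    def test_roved_needs_prior_sd(self):
        with pytest.raises(ValueError):
            Parameter("a", 1.0, role="roved")

    def test_prior_info_matrix_layout(self):
        pspec = ParameterSpec(
            (
                Parameter("f", 1000.0, role="target"),
                Parameter("L", 30.0, role="fixed"),
                Parameter("phi", 0.0, role="roved", prior_sd=2 * np.pi),
            )
        )
        a = prior_info_matrix(pspec)
        assert a.shape == (2, 2)  # target + roved only
        assert a[0, 0] == 0.0
        assert a[1, 1] == pytest.approx(1 / (2 * np.pi) ** 2)

    def test_cached_rate_function_caches(self):
        calls = []

        def rate_fn(theta):
            calls.append(tuple(theta))
            return constant_rate_fn(theta)

        cached = cached_rate_function(rate_fn)
        cached(np.array([100.0]))
        cached(np.array([100.0]))
        cached(np.array([101.0]))
        assert len(calls) == 2
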