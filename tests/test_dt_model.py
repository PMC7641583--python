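"""Direct-transport model: transport factor, lengthscale, profile, precision."""

import numpy as np
import pytest
import warnings
from hypothesis import given, settings, strategies as st

import morphosense as ms
from morphosense.dt_model import solve_dplus_powerlaw


class TestGammaProfile:
    def test_constant_limit_strong_backward_bias(self):
        # phi << -1: every cell receives the same flux, Gamma_j -> 1
        shape = ms.DTShape.from_lengthscale(-10.0, 10.0, 100)
        G = ms.gamma_profile(shape, np.arange(1, 101))
        assert np.all(np.abs(G - 1.0) < 1e-4)

    def test_exponential_limit_strong_forward_bias(self):
        shape = ms.DTShape(phi=10.0, lambda_hat=ms.lengthscale_dt(10.0, 0.1),
                           N=100, kappa_a=0.1)
        assert ms.gamma_profile(shape, 5) == pytest.approx(np.exp(-1.0),
                                                           rel=1e-3)

    def test_source_end_identity(self):
        # j = 0 formally gives Gamma_0 = 1 for any parameters
        for phi in (-3.0, 0.7, 12.0):
            shape = ms.DTShape.from_lengthscale(phi, 7.0, 50)
            assert ms.gamma_profile(shape, 0) == pytest.approx(1.0)

    @given(phi=st.floats(-10, 10).filter(lambda p: abs(p) > 1e-3),
           lam=st.floats(0.5, 100))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_bounded_and_monotone(self, phi, lam):
        shape = ms.DTShape.from_lengthscale(phi, lam, 200)
        G = ms.gamma_profile(shape, np.arange(1, 201))
        # steep profiles may underflow to exactly 0 at distant cells; Gamma
        # must be positive wherever its leading exponent is representable
        assert np.all(G >= 0) and np.all(G <= 1.0 + 1e-12)
        j = np.arange(1, 201)
        representable = 2.0 * j * abs(shape.kappa_a) < 700.0
        assert np.all(G[representable] > 0)
        assert np.all(np.diff(G) <= 1e-12)

    def test_extreme_phi_no_overflow(self):
        # log-domain evaluation: |phi| = 800 must not produce inf/nan
        shape = ms.DTShape.from_lengthscale(-800.0, 5.0, 50)
        G = ms.gamma_profile(shape, np.arange(1, 51))
        assert np.all(np.isfinite(G)) and np.all(np.abs(G - 1) < 1e-6)


class TestLengthscale:
    @given(phi=st.floats(-10, 10).filter(lambda p: abs(p) > 1e-3),
           lam=st.floats(0.5, 100))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_round_trip(self, phi, lam):
        ka = ms.solve_kappa(phi, lam)
        assert np.sign(ka) == np.sign(phi)
        assert ms.lengthscale_dt(phi, ka) == pytest.approx(lam, rel=1e-6)

    def test_large_phi_limit_is_pure_exponential(self):
        # phi -> infinity: lambda_hat -> 1/|kappa a|
        assert ms.lengthscale_dt(40.0, 0.05) == pytest.approx(20.0, rel=1e-6)
        assert ms.solve_kappa(10.0, 10.0) == pytest.approx(0.1, rel=1e-3)

    def test_closed_form_equals_quadrature(self):
        # the product form is the exact continuum integral of Gamma(j)
        shape = ms.DTShape(phi=1.0, lambda_hat=ms.lengthscale_dt(1.0, 0.05),
                           N=500, kappa_a=0.05)
        lam = np.expm1(1.0) * (1.0 - np.log(np.expm1(1.0))) / 0.05
        assert shape.lambda_hat == pytest.approx(lam, rel=1e-12)
        assert ms.lengthscale_dt_quadrature(shape) == pytest.approx(lam,
                                                                    rel=2e-2)

    @pytest.mark.parametrize("phi", [0.1, 1.0, 5.0])
    @pytest.mark.parametrize("lam", [5.0, 20.0, 50.0])
    def test_quadrature_grid(self, phi, lam):
        shape = ms.DTShape.from_lengthscale(phi, lam, 1000)
        assert ms.lengthscale_dt_quadrature(shape) == pytest.approx(lam,
                                                                    rel=0.05)

    def test_integer_sum_bias_shrinks_with_lengthscale(self):
        # the literal per-integer sum overestimates by O(1/lambda_hat)
        devs = []
        for lam in (5.0, 20.0, 80.0):
            shape = ms.DTShape.from_lengthscale(5.0, lam, 2000)
            devs.append(ms.lengthscale_dt_discrete(shape) / lam - 1.0)
        assert all(d > 0 for d in devs)
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.02

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ms.lengthscale_dt(1.0, 0.0)
        with pytest.raises(ValueError):
            ms.lengthscale_dt(1.0, -0.1)  # sign mismatch
        assert ms.solve_kappa(0.0, 10.0) == 0.0


class TestPowerLawBranch:
    def test_dplus_reproduces_requested_lengthscale(self):
        for lam in (3.0, 10.0, 40.0):
            shape = ms.DTShape.from_lengthscale(0.0, lam, 100)
            assert shape.powerlaw
            assert ms.lengthscale_dt_quadrature(shape) == pytest.approx(
                lam, rel=1e-6)

    def test_power_law_form(self):
        shape = ms.DTShape.from_lengthscale(0.0, 10.0, 100)
        d = shape.d_plus_over_a
        j = np.arange(1, 101)
        assert ms.gamma_profile(shape, j) == pytest.approx(1 / (1 + 2 * j / d))

    def test_small_phi_profile_agrees_at_moderate_j(self):
        # just above the branch threshold the closed form is still close to
        # the power law at small j (before the exponential cutoff bites)
        closed = ms.DTShape.from_lengthscale(0.01, 10.0, 100)
        power = ms.DTShape.from_lengthscale(0.0, 10.0, 100)
        j = np.arange(1, 11)
        gc = ms.gamma_profile(closed, j)
        gp = ms.gamma_profile(power, j)
        assert np.max(np.abs(gc / gp - 1)) < 0.06


class TestMeanProfile:
    @pytest.mark.parametrize("phi,lam", [(-4.0, 3.0), (0.5, 10.0), (6.0, 30.0)])
    def test_conservation(self, phi, lam):
        # total mean count over all 2N target cells balances production
        shape = ms.DTShape.from_lengthscale(phi, lam, 80)
        rates = ms.DTRates(beta=37.0, nu=1.7, T=100.0)
        prof = ms.mean_profile_dt(shape, rates)
        assert 2.0 * prof.values.sum() == pytest.approx(37.0 / 1.7, rel=1e-12)

    def test_profile_monotone(self):
        shape = ms.DTShape.from_lengthscale(2.0, 8.0, 50)
        prof = ms.mean_profile_dt(shape, ms.DTRates(beta=100, nu=1, T=50))
        assert np.all(prof.delta >= 0)


class TestPrecision:
    def test_zero_steepness_constant_profile(self):
        shape = ms.DTShape.from_lengthscale(-10.0, 10.0, 50)
        res = ms.precision_dt(shape, ms.DTRates(beta=10, nu=1, T=100))
        assert np.all(res.p_squared < 1e-7)

    def test_nu_invariance_at_fixed_beta_T(self):
        # P^2 depends on beta*T, not on nu: mean ~ 1/nu, refresh ~ nu
        shape = ms.DTShape.from_lengthscale(1.0, 10.0, 100)
        ref = None
        for nu in (0.1, 1.0, 10.0):
            res = ms.precision_dt(shape, ms.DTRates(beta=5.0, nu=nu, T=200.0))
            if ref is None:
                ref = res.p_squared
            else:
                np.testing.assert_allclose(res.p_squared, ref, rtol=1e-10)

    def test_short_window_warns(self):
        with pytest.warns(UserWarning, match="T.*nu"):
            ms.DTRates(beta=1.0, nu=1.0, T=2.0)


class TestOptimizePhi:
    @pytest.mark.parametrize("lam", [1.0, 2.0, 5.0, 10.0, 20.0, 50.0])
    def test_optimum_positive(self, lam):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary warning at large lam
            phi_star, p2 = ms.optimize_phi(100, 50, lam)
        assert phi_star > 0 and p2 > 0

    def test_beats_dense_grid(self):
        phi_star, p2_star = ms.optimize_phi(100, 50, 10.0)
        grid = np.logspace(-3, np.log10(30.0), 2000)
        from morphosense.dt_model import _p2_at
        dense = max(_p2_at(p, 10.0, 100, 50) for p in grid)
        assert p2_star >= dense - 1e-9

    def test_stable_under_grid_refinement(self):
        a, _ = ms.optimize_phi(100, 50, 10.0, n_grid=400)
        b, _ = ms.optimize_phi(100, 50, 10.0, n_grid=800)
        assert abs(a / b - 1) < 0.01
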