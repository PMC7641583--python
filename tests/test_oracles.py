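"""Stochastic oracles: seeded simulators validating the closed forms.

These are the fast unit-level versions; the heavier study-scale runs live in
the acceptance suite.
"""

import numpy as np
import pytest
from scipy.stats import kstest

import morphosense as ms
from morphosense.stochastic_oracles import (CytonemeMicroParams,
                                            DeterministicDelay,
                                            ExponentialDelay,
                                            SimConfig,
                                            TelegraphFirstPassageDelay,
                                            arrival_vs_concentration_cv,
                                            integrate_cytoneme_ode,
                                            simulate_birth_death,
                                            simulate_generalized_dt,
                                            simulate_hopping_chain,
                                            simulate_sdc_lattice)


@pytest.fixture(scope="module")
def bd_stats():
    cfg = SimConfig(seed=42, total_time=2020.0, burn_in=20.0,
                    n_replicates=32, sample_interval=2.0)
    return simulate_birth_death(30.0, 1.0, cfg)


class TestBirthDeath:

    def test_stationary_mean(self, bd_stats):
        s = bd_stats
        assert abs(s.stationary_mean - 30.0) < 3 * s.stationary_mean_se

    def test_poisson_fano(self, bd_stats):
        dev = bd_stats.stationary_variance - bd_stats.stationary_mean
        assert abs(dev) < 3 * bd_stats.stationary_variance_se

    def test_time_average_variance_coefficient(self, bd_stats):
        # sigma^2 * T / (m * tau) -> 2 with tau = 1/death
        s = bd_stats
        ratio = s.time_avg_variance * s.window / s.stationary_mean
        se = s.time_avg_variance_se * s.window / s.stationary_mean
        assert abs(ratio - 2.0) < 3 * se

    def test_reproducible(self):
        cfg = SimConfig(seed=7, total_time=60.0, burn_in=10.0,
                        n_replicates=3, sample_interval=1.0)
        a = simulate_birth_death(10.0, 1.0, cfg)
        b = simulate_birth_death(10.0, 1.0, cfg)
        assert a.stationary_mean == b.stationary_mean
        assert a.time_avg_variance == b.time_avg_variance


class TestGeneralizedDT:
    def test_delay_law_irrelevance(self):
        # deterministic vs exponential delay of the same mean: identical
        # stationary mean and Fano factor (birth-death equivalence theorem)
        out = {}
        for name, sampler in [("det", DeterministicDelay(5.0)),
                              ("exp", ExponentialDelay(5.0))]:
            cfg = SimConfig(seed=11, total_time=220.0, burn_in=20.0,
                            n_replicates=48, sample_interval=2.0)
            out[name] = simulate_generalized_dt(20.0, sampler, 1.0, cfg)
        d, e = out["det"], out["exp"]
        se_mean = np.hypot(d.stationary_mean_se, e.stationary_mean_se)
        assert abs(d.stationary_mean - e.stationary_mean) < 3 * se_mean
        for s in (d, e):
            assert abs(s.stationary_mean - 20.0) < 3 * s.stationary_mean_se
            dev = s.stationary_variance - s.stationary_mean
            assert abs(dev) < 3 * s.stationary_variance_se

    def test_arrival_process_is_poisson(self):
        cfg = SimConfig(seed=9, total_time=520.0, burn_in=20.0,
                        n_replicates=1, sample_interval=5.0)
        _, extra = simulate_generalized_dt(20.0, ExponentialDelay(3.0), 1.0,
                                           cfg, return_arrivals=True)
        inter = np.diff(extra["arrivals"])
        assert inter.size > 5000
        # KS distance below the 1% critical value c(0.01)/sqrt(n)
        d = kstest(inter, "expon", args=(0.0, 1.0 / 20.0)).statistic
        assert d < 1.628 / np.sqrt(inter.size)

    def test_telegraph_delay_sampler(self):
        tg = TelegraphFirstPassageDelay(1.0, 1.0, 1.0 / 17.3, 1.0 / 127.8,
                                        length=10.0)
        rng = np.random.default_rng(0)
        d = tg(rng, 500)
        assert np.all(d >= 10.0)  # cannot beat ballistic transit
        cfg = SimConfig(seed=13, total_time=160.0, burn_in=60.0,
                        n_replicates=24, sample_interval=2.0)
        s = simulate_generalized_dt(15.0, tg, 1.0, cfg)
        assert abs(s.stationary_mean - 15.0) < 3 * s.stationary_mean_se
        dev = s.stationary_variance - s.stationary_mean
        assert abs(dev) < 3 * s.stationary_variance_se

    def test_routed_means_match_closed_form(self):
        shape = ms.DTShape.from_lengthscale(2.0, 8.0, 25)
        G = ms.gamma_profile(shape, np.arange(1, 26))
        pi = np.concatenate([G, G]) / (2 * G.sum())
        cfg = SimConfig(seed=12, total_time=120.0, burn_in=20.0,
                        n_replicates=40, sample_interval=2.0)
        _, extra = simulate_generalized_dt(100.0, ExponentialDelay(2.0), 1.0,
                                           cfg, routing=pi)
        mth = ms.mean_profile_dt(shape,
                                 ms.DTRates(beta=100.0, nu=1.0, T=100.0)).values
        z = (extra["cell_means"][:25] - mth) / extra["cell_means_se"][:25]
        assert np.all(np.abs(z) < 3.5)

    def test_negative_delay_rejected(self):
        cfg = SimConfig(seed=1, total_time=40.0, burn_in=10.0,
                        n_replicates=2, sample_interval=1.0)
        bad = lambda rng, n: np.full(n, -1.0)
        with pytest.raises(ValueError, match="negative"):
            simulate_generalized_dt(5.0, bad, 1.0, cfg)


@pytest.fixture(scope="module")
def cyto_setup():
    lam = ms.lengthscale_dt(2.0, 0.05)
    shape = ms.DTShape(phi=2.0, lambda_hat=lam, N=10, kappa_a=0.05)
    rates = ms.DTRates(beta=100.0, nu=1.0, T=100.0)
    micro = CytonemeMicroParams.from_shape(shape, rates)
    closed = ms.mean_profile_dt(shape, rates).values
    return micro, closed


class TestCytonemeODE:
    def test_steady_state_matches_closed_form(self, cyto_setup):
        micro, closed = cyto_setup
        prof = integrate_cytoneme_ode(micro, grid_points=120)
        assert np.max(np.abs(prof.values / closed - 1)) < 0.005

    def test_flux_balance(self, cyto_setup):
        micro, _ = cyto_setup
        prof = integrate_cytoneme_ode(micro, grid_points=120)
        assert 2 * micro.nu * prof.values.sum() == pytest.approx(
            micro.beta, rel=1e-3)

    def test_grid_convergence(self, cyto_setup):
        micro, _ = cyto_setup
        a = integrate_cytoneme_ode(micro, grid_points=120).values
        b = integrate_cytoneme_ode(micro, grid_points=240).values
        assert np.max(np.abs(b / a - 1)) < 1e-3

    def test_micro_params_realise_shape(self, cyto_setup):
        micro, _ = cyto_setup
        assert micro.phi == pytest.approx(2.0, rel=1e-12)
        assert micro.kappa_a == pytest.approx(0.05, rel=1e-12)


class TestSDCLattice:
    def test_means_ratio_and_conservation(self):
        cfg = SimConfig(seed=3, total_time=58.0, burn_in=8.0,
                        n_replicates=32, sample_interval=1.0)
        res = simulate_sdc_lattice(beta=200.0, D=25.0, nu=1.0, a=1.0,
                                   n_cells=16, subcells_per_cell=8,
                                   config=cfg, probe_cells=(2, 3))
        assert abs(res.total_mean - 200.0) < 3 * res.total_mean_se
        s2, s3 = res.per_cell[2], res.per_cell[3]
        ratio = s3.stationary_mean / s2.stationary_mean
        se = ratio * np.hypot(s2.stationary_mean_se / s2.stationary_mean,
                              s3.stationary_mean_se / s3.stationary_mean)
        assert abs(ratio - np.exp(-2.0 / 5.0)) < 3 * se

    def test_boundary_guard(self):
        cfg = SimConfig(seed=1, total_time=20.0, burn_in=5.0,
                        n_replicates=2, sample_interval=1.0)
        with pytest.raises(ValueError, match="5 lambda"):
            simulate_sdc_lattice(beta=10.0, D=100.0, nu=1.0, a=1.0,
                                 n_cells=5, subcells_per_cell=4, config=cfg)


class TestHoppingChain:
    def test_autocovariance_matches_bessel_form(self):
        cfg = SimConfig(seed=17, total_time=1210.0, burn_in=10.0,
                        n_replicates=32, sample_interval=0.25)
        stats = simulate_hopping_chain(beta=50.0, h=1.0, nu=1.0, n_sites=101,
                                       config=cfg, max_lag=8)
        m = stats.stationary_mean
        p = ms.HoppingParams(h=1.0, nu=1.0, m_j=m)
        pred = ms.autocorrelation_hopping(p, stats.autocov_lags)
        for lag_i in (1, 2, 4, 8):   # t = 0.25 .. 2.0
            z = (stats.autocov[lag_i] - pred[lag_i]) / stats.autocov_se[lag_i]
            assert abs(z) < 3.0, f"lag {stats.autocov_lags[lag_i]}: z={z}"


class TestArrivalVsConcentration:
    def test_ratio_and_poisson_arrivals(self):
        cfg = SimConfig(seed=23, total_time=520.0, burn_in=20.0,
                        n_replicates=120, sample_interval=5.0)
        res = arrival_vs_concentration_cv(50.0, 1.0, cfg)
        assert abs(res.ratio - 2.0) < 3 * res.ratio_se
        # arrival-count readout: squared CV = 1/(birth * T)
        assert res.cv2_arrival == pytest.approx(1.0 / (50.0 * 500.0),
                                                rel=0.45)

    def test_ratio_invariant_to_birth_rate(self):
        vals = []
        for i, birth in enumerate((20.0, 200.0)):
            cfg = SimConfig(seed=31 + i, total_time=260.0, burn_in=10.0,
                            n_replicates=100, sample_interval=5.0)
            vals.append(arrival_vs_concentration_cv(birth, 1.0, cfg))
        se = np.hypot(vals[0].ratio_se, vals[1].ratio_se)
        assert abs(vals[0].ratio - vals[1].ratio) < 3 * se
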