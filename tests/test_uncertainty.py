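"""Covariance spectra, misfit geometry and noise-energy bookkeeping."""

import numpy as np
import pytest

from condassim.errors import InvalidParameterError
from condassim.uncertainty import (
    LinearForwardModel,
    ODEForwardModel,
    covariance_and_spectrum,
    misfit_terms,
    noise_energy_and_temperature,
    parameter_offset,
    pdf_summary,
)


class TestCovariance:
    def test_two_point_hand_example(self):
        # rows p and -p in 2-D: Sigma = 2 [[p1^2, p1 p2], [p1 p2, p2^2]]
        p = np.array([1.5, -0.4])
        Sigma, lam2 = covariance_and_spectrum(np.vstack([p, -p]))
        assert np.allclose(Sigma, 2.0 * np.outer(p, p))
        assert lam2[0] == pytest.approx(2 * p @ p)
        assert lam2[1] == pytest.approx(0.0, abs=1e-12)

    def test_identical_rows_zero_matrix(self):
        P = np.tile([3.0, 1.0, -2.0], (5, 1))
        Sigma, lam2 = covariance_and_spectrum(P)
        assert np.allclose(Sigma, 0.0)

    def test_psd_and_order_invariance(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(40, 5))
        Sigma, lam2 = covariance_and_spectrum(P)
        assert np.all(lam2 >= -1e-12)
        assert np.all(np.diff(lam2) <= 1e-12)  # descending
        perm = rng.permutation(5)
        _, lam2p = covariance_and_spectrum(P[:, perm])
        assert np.allclose(np.sort(lam2), np.sort(lam2p))

    def test_linear_gaussian_matches_closed_form(self):
        # ensemble of least-squares fits vs sigma^2 (X^T X)^{-1}
        rng = np.random.default_rng(11)
        n, K, R, sigma = 60, 3, 400, 0.3
        X = rng.normal(size=(n, K))
        fm = LinearForwardModel(X)
        p_true = np.array([1.0, -2.0, 0.5])
        V0 = fm.values(p_true)
        fits = np.array([fm.fit(V0 + sigma * rng.standard_normal(n)) for _ in range(R)])
        Sigma, _ = covariance_and_spectrum(fits)
        ref = sigma**2 * np.linalg.inv(X.T @ X)
        assert np.allclose(Sigma, ref, atol=6 * np.abs(ref).max() / np.sqrt(R))

    def test_needs_two_rows(self):
        with pytest.raises(InvalidParameterError):
            covariance_and_spectrum(np.ones((1, 3)))


class TestMisfitGeometry:
    def test_error_free_limit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        fm = LinearForwardModel(X)
        p = rng.normal(size=4)
        geom = misfit_terms(fm, p, V_exp=fm.values(p))
        assert geom.F == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(geom.G, 0.0)
        assert np.allclose(geom.H, X.T @ X)  # pure Gauss-Newton term

    def test_offset_matches_direct_reminimization(self):
        # linear-Gaussian: the quadratic expansion is exact, so -H^{-1} G
        # equals the shift of the re-solved minimum to machine precision
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 3))
        fm = LinearForwardModel(X)
        p_star = np.array([0.3, 1.1, -0.8])
        V_use = fm.values(p_star)
        eps = 0.2 * rng.standard_normal(50)
        geom = misfit_terms(fm, p_star, V_exp=V_use + eps, V_use=V_use)
        dp = parameter_offset(geom)
        p_noisy = fm.fit(V_use + eps)
        assert np.allclose(dp, p_noisy - p_star, atol=1e-8)

    def test_scalar_offset_is_g_over_h(self):
        fm = LinearForwardModel(np.array([[2.0]]))
        geom = misfit_terms(fm, np.array([1.0]), V_exp=np.array([2.5]))
        # V = 2p, p* = 1, observation 2.5: the re-solved minimum is p = 1.25,
        # i.e. the offset G/H = (2*0.5)/4 = 0.25
        assert parameter_offset(geom)[0] == pytest.approx(geom.G[0] / geom.H[0, 0])
        assert parameter_offset(geom)[0] == pytest.approx(0.25)

    def test_zero_gradient_zero_offset(self):
        fm = LinearForwardModel(np.eye(3))
        geom = misfit_terms(fm, np.zeros(3), V_exp=np.zeros(3))
        assert np.allclose(parameter_offset(geom), 0.0)

    def test_ode_sensitivities_match_finite_differences(self, leak):
        from condassim.twin import build_step_protocol

        model, table = leak
        proto = build_step_protocol([(10, 0), (20, 1500)])
        t = np.linspace(0, 30, 61)
        free = ("E_Leak", "g_L")
        fm = ODEForwardModel(
            model, proto, t, table.p_true, free_names=free, rtol=1e-10, atol=1e-12
        )
        p = np.array([table.p_true[k] for k in free])
        J = fm.jacobian(p)
        # step large enough that integrator error does not dominate the
        # difference quotient; the map is near-linear over this range
        for k in range(2):
            h = 1e-3 * max(abs(p[k]), 1.0)
            pp, pm = p.copy(), p.copy()
            pp[k] += h
            pm[k] -= h
            fd = (fm.values(pp) - fm.values(pm)) / (2 * h)
            assert np.max(np.abs(J[:, k] - fd)) < 1e-5 * max(1.0, np.abs(fd).max())

    def test_misfit_gradient_matches_cost_cross_term_fd(self, leak):
        # G_k must equal the gradient of sum eps*(V(p)-V_use) by definition
        from condassim.twin import build_step_protocol

        model, table = leak
        proto = build_step_protocol([(10, 0), (15, 1000)])
        t = np.linspace(0, 25, 51)
        free = ("E_Leak", "g_L")
        fm = ODEForwardModel(model, proto, t, table.p_true, free_names=free)
        p_star = np.array([table.p_true[k] for k in free])
        V_use = fm.values(p_star)
        rng = np.random.default_rng(9)
        eps = 0.5 * rng.standard_normal(len(t))
        geom = misfit_terms(
            fm, p_star, V_exp=V_use + eps, V_use=V_use, include_second_order=False
        )
        for k in range(2):
            h = 1e-5 * max(abs(p_star[k]), 1.0)
            pp, pm = p_star.copy(), p_star.copy()
            pp[k] += h
            pm[k] -= h
            cross = lambda q: float(eps @ (fm.values(q) - V_use))
            fd = (cross(pp) - cross(pm)) / (2 * h)
            assert geom.G[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestNoiseEnergy:
    def test_zero_and_quadratic_scaling(self):
        e0, T0 = noise_energy_and_temperature(0.0, 1000, 1e8, 1e4)
        assert e0 == 0.0 and T0 == 0.0
        e1, T1 = noise_energy_and_temperature(0.5, 1000, 1e8, 1e4)
        e2, T2 = noise_energy_and_temperature(1.0, 1000, 1e8, 1e4)
        assert e2 == pytest.approx(4 * e1)
        assert T2 == pytest.approx(4 * T1)

    def test_monte_carlo_mean_of_noise_energy(self):
        # E[1/2 sum eps^2] = (n+1) sigma^2 / 2 within 3 standard errors
        from condassim.twin import sample_noise

        n, sigma, R = 500, 0.4, 1000
        vals = np.array(
            [0.5 * np.sum(sample_noise(sigma, z, n + 1) ** 2) for z in range(R)]
        )
        expect = (n + 1) * sigma**2 / 2
        se = np.std(vals, ddof=1) / np.sqrt(R)
        assert abs(np.mean(vals) - expect) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            noise_energy_and_temperature(0.5, 100, -1.0, 1e4)


class TestPdfSummary:
    def test_gaussian_recovery(self):
        rng = np.random.default_rng(21)
        mu, sd = 3.0, 0.2
        x = rng.normal(mu, sd, size=4000)
        s = pdf_summary(x)
        assert s["mle"] == pytest.approx(mu, abs=3 * sd / np.sqrt(4000) * 5)
        assert s["sigma_p"] == pytest.approx(sd, rel=0.05)
        assert not s["non_gaussian"]

    def test_skewed_sample_flagged(self):
        rng = np.random.default_rng(22)
        x = rng.lognormal(0.0, 0.8, size=2000)
        assert pdf_summary(x)["non_gaussian"]

    def test_constant_sample(self):
        s = pdf_summary(np.full(50, 1.23))
        assert s["sigma_p"] == 0.0

    def test_too_few_samples(self):
        with pytest.raises(InvalidParameterError):
            pdf_summary(np.arange(10))
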