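"""Priors, exact posterior/predictive quadrature vs conjugate closed forms,
and the Laplace expansions."""

import numpy as np
import pytest
from scipy import integrate

import censgeom as cg
from conftest import make_sample_with_stat


class TestJeffreysPrior:
    def test_rayleigh_score_of_prior(self, rayleigh, table2_scheme):
        """pi_J(lam) proportional to 1/lam, so d log pi = -1/lam."""
        jp = cg.jeffreys_prior(rayleigh, table2_scheme)
        for lam in (0.3, 1.0, 2.0):
            assert np.isclose(jp.dlog_pdf([lam])[0], -1.0 / lam)

    def test_exponential_same_form(self, exponential, table2_scheme):
        jp = cg.jeffreys_prior(exponential, table2_scheme)
        assert np.isclose(jp.dlog_pdf([1.5])[0], -1.0 / 1.5)

    def test_half_skewness_identity(self, rayleigh, table2_scheme):
        """d_i log pi_J - Gamma^{e,j}_{ij} = T_i / 2 (the e-connection term is 0)."""
        lam = 0.9
        jp = cg.jeffreys_prior(rayleigh, table2_scheme)
        geo = cg.geometry_tensors(rayleigh, [lam], table2_scheme, alpha=1.0)
        gamma_e_contr = np.einsum("ijj->i", geo.Gamma_alpha_mixed)
        lhs = jp.dlog_pdf([lam]) - gamma_e_contr
        assert np.allclose(lhs, 0.5 * geo.T_contr)
        assert np.isclose(lhs[0], -1.0 / lam)


class TestExactPosterior:
    def test_matches_conjugate_gamma(self, rayleigh, table2):
        m = table2.scheme.m
        S = cg.rayleigh_sufficient_stat(table2)
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        grid = np.linspace(0.002, 0.08, 40)
        quad_post = cg.posterior_exact(table2, rayleigh, jp, grid)
        closed = cg.rayleigh_conjugate_posterior(grid, m, S)
        assert np.max(np.abs(quad_post - closed)) / closed.max() < 1e-6

    def test_single_observation_unit_posterior(self, rayleigh):
        """m=1, x=1, Jeffreys: posterior is Gamma(1,1), density e^{-lam}."""
        sch = cg.validate_scheme(1, 1, (0,))
        samp = cg.ProgressiveSample(sch, np.array([1.0]))
        jp = cg.jeffreys_prior(rayleigh, sch)
        grid = np.array([0.1, 0.5, 1.0, 2.0])
        assert np.allclose(
            cg.posterior_exact(samp, rayleigh, jp, grid), np.exp(-grid), atol=1e-8
        )

    def test_uniform_prior_truncates(self, rayleigh, table2):
        up = cg.uniform_prior(0.0, 0.03)
        vals = cg.posterior_exact(table2, rayleigh, up, np.array([0.01, 0.05]))
        assert vals[0] > 0 and vals[1] == 0.0

    def test_posterior_integrates_to_one(self, rayleigh, table2):
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        total, _ = integrate.quad(
            lambda t: float(cg.posterior_exact(table2, rayleigh, jp, [t])[0]),
            0,
            np.inf,
            limit=200,
        )
        assert abs(total - 1.0) < 1e-8


class TestExactPredictive:
    def test_matches_conjugate_closed_form(self, rayleigh, table2):
        m, S = table2.scheme.m, cg.rayleigh_sufficient_stat(table2)
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        x = np.array([0.5, 2.8, 6.0, 12.0])
        assert np.max(np.abs(
            cg.predictive_exact(table2, rayleigh, jp, x)
            - cg.rayleigh_conjugate_predictive(x, m, S)
        )) < 1e-8

    def test_unit_case_value(self):
        assert np.isclose(cg.rayleigh_conjugate_predictive(1.0, 1, 1.0), 0.5)

    def test_predictive_integrates_to_one(self, table2):
        m, S = table2.scheme.m, cg.rayleigh_sufficient_stat(table2)
        total, _ = integrate.quad(
            lambda x: float(cg.rayleigh_conjugate_predictive(x, m, S)), 0, np.inf,
            limit=200,
        )
        assert abs(total - 1.0) < 1e-10

    def test_uniform_prior_closed_form_vs_quadrature(self, rayleigh, table2):
        m, S = table2.scheme.m, cg.rayleigh_sufficient_stat(table2)
        up = cg.uniform_prior(0.0, 3.0)
        x = np.array([0.8, 2.8, 5.0])
        assert np.allclose(
            cg.predictive_exact(table2, rayleigh, up, x),
            cg.rayleigh_uniform_predictive(x, m, S, 3.0),
            atol=1e-10,
        )


class TestPosteriorExpansion:
    def test_value_at_mode(self, rayleigh, table2):
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        lam_hat = cg.fit_mle(table2, rayleigh)[0]
        m = table2.scheme.m
        expected = np.sqrt(m / lam_hat**2 / (2 * np.pi))
        assert np.isclose(cg.posterior_expansion(table2, rayleigh, jp, [lam_hat])[0],
                          expected)

    def test_bracket_taylor_coefficients(self, rayleigh, table2):
        """The bracket is 1 + (m/(3 lam^3)) tt^3 - tt/lam at the MLE, matching
        the cubic Taylor term of the exact Gamma(m,S) log-posterior."""
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        lam_hat = cg.fit_mle(table2, rayleigh)[0]
        m = table2.scheme.m
        lead = np.sqrt(m / lam_hat**2 / (2 * np.pi))
        for tt in (-0.3 * lam_hat, 0.2 * lam_hat):
            lam = lam_hat + tt
            val = cg.posterior_expansion(table2, rayleigh, jp, [lam])[0]
            gauss = lead * np.exp(-0.5 * (m / lam_hat**2) * tt**2)
            bracket = 1.0 + m / (3 * lam_hat**3) * tt**3 - tt / lam_hat
            assert np.isclose(val, gauss * bracket, rtol=1e-12)

    def test_error_decreases_with_m(self, rayleigh):
        errs = []
        for m in (10, 40, 160):
            samp = make_sample_with_stat(m, 2 * m, S=float(m))
            jp = cg.jeffreys_prior(rayleigh, samp.scheme)
            lam_hat = cg.fit_mle(samp, rayleigh)[0]
            sd = lam_hat / np.sqrt(m)
            grid = np.linspace(max(lam_hat - 3 * sd, 1e-8), lam_hat + 3 * sd, 150)
            approx = cg.posterior_expansion(samp, rayleigh, jp, grid)
            exact = cg.rayleigh_conjugate_posterior(
                grid, m, cg.rayleigh_sufficient_stat(samp)
            )
            errs.append(np.max(np.abs(approx - exact)))
        assert errs[0] > errs[1] > errs[2]


class TestPredictiveExpansion:
    def test_corrected_rayleigh_jeffreys_closed_form(self, rayleigh, table2):
        """b = 0 under Jeffreys, leaving f(x;lam)(1 + (u^2/2 - u)/m), u = lam x^2;
        at u = 2 the expansion crosses the plug-in exactly."""
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        m = table2.scheme.m
        x = np.array([0.5, 2.0, 4.0, 9.0])
        res = cg.predictive_expansion(table2, rayleigh, jp, x, mode="corrected")
        lam_hat = res.theta_hat[0]
        u = lam_hat * x**2
        assert np.allclose(res.terms["b"], 0.0, atol=1e-14)
        assert np.allclose(res.value, res.plug_in * (1 + (u**2 / 2 - u) / m))
        x_cross = np.sqrt(2.0 / lam_hat)
        res_cross = cg.predictive_expansion(table2, rayleigh, jp, x_cross, mode="corrected")
        assert np.isclose(res_cross.value[0], res_cross.plug_in[0], rtol=1e-12)

    def test_corrected_correction_integrates_to_zero(self, rayleigh, table2):
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)

        def corr(x):
            res = cg.predictive_expansion(table2, rayleigh, jp, x, mode="corrected")
            return float(res.value[0] - res.plug_in[0])

        total, _ = integrate.quad(corr, 0, np.inf, limit=200)
        assert abs(total) < 1e-10

    def test_corrected_error_scales_as_m_squared(self, rayleigh):
        errs = {}
        xg = np.linspace(0.01, 4.0, 200)
        for m in (20, 40, 80, 160):
            samp = make_sample_with_stat(m, 2 * m, S=float(m))  # lam_hat = 1
            jp = cg.jeffreys_prior(rayleigh, samp.scheme)
            exact = cg.rayleigh_conjugate_predictive(
                xg, m, cg.rayleigh_sufficient_stat(samp)
            )
            res = cg.predictive_expansion(samp, rayleigh, jp, xg, mode="corrected")
            errs[m] = np.max(np.abs(res.value - exact))
        for m in (20, 40, 80):
            assert 3.3 <= errs[m] / errs[2 * m] <= 4.8

    def test_paper_mode_constant_offset(self, rayleigh, table2):
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        m, n = table2.scheme.m, table2.scheme.n
        x = np.array([0.4, 1.0, 2.8, 7.0])
        res = cg.predictive_expansion(table2, rayleigh, jp, x, mode="paper")
        assert np.allclose(res.value - res.plug_in, 1.0 / (4 * m * n), atol=1e-15)

    def test_paper_mode_marginal_informed_collapse(self, rayleigh, table2):
        """The double-sum identity makes the marginal-informed correction term
        vanish, leaving the same constant offset."""
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        m, n = table2.scheme.m, table2.scheme.n
        x = np.array([0.4, 2.8])
        res = cg.predictive_expansion(
            table2, rayleigh, jp, x, mode="paper", marginal_informed=True
        )
        assert np.allclose(res.value - res.plug_in, 1.0 / (4 * m * n), atol=1e-12)

    def test_paper_mode_restricted(self, exponential, table2_scheme):
        samp = cg.draw_progressive_sample(exponential, [1.0], table2_scheme, seed=1)
        jp = cg.jeffreys_prior(exponential, table2_scheme)
        with pytest.raises(ValueError, match="paper"):
            cg.predictive_expansion(samp, exponential, jp, 1.0, mode="paper")

    def test_unknown_mode(self, rayleigh, table2):
        jp = cg.jeffreys_prior(rayleigh, table2.scheme)
        with pytest.raises(ValueError, match="mode"):
            cg.predictive_expansion(table2, rayleigh, jp, 1.0, mode="bogus")


class TestPlugIn:
    def test_value(self, rayleigh):
        sch = cg.validate_scheme(1, 1, (0,))
        samp = cg.ProgressiveSample(sch, np.array([1.0]))  # lam_hat = 1
        assert np.isclose(cg.plug_in_density(samp, rayleigh, 1.0), 2 * np.e**-1)

    def test_invariance_under_reparameterization(self, rayleigh, exponential, table2):
        """The Rayleigh analysis of x equals the exponential analysis of x^2:
        the plug-in densities agree through the change of variables."""
        sq = cg.ProgressiveSample(table2.scheme, table2.x**2)
        lam_ray = cg.fit_mle(table2, rayleigh)[0]
        lam_exp = cg.fit_mle(sq, exponential)[0]
        assert np.isclose(lam_ray, lam_exp)
        x = 2.8
        assert np.isclose(
            float(cg.plug_in_density(table2, rayleigh, x)),
            2 * x * float(cg.plug_in_density(sq, exponential, x**2)),
        )

    def test_table2_value_at_2p8(self, rayleigh, table2):
        lam_hat = cg.fit_mle(table2, rayleigh)[0]
        expected = 2 * lam_hat * 2.8 * np.exp(-lam_hat * 2.8**2)
        val = float(cg.plug_in_density(table2, rayleigh, 2.8))
        assert np.isclose(val, expected)
        assert 0.08 < val < 0.10  # ~0.0906 for the breakdown data
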