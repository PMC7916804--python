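"""Branch-level transitions: exact steps, Simpson integrals, the A term.

Monte Carlo checks compare path-based samples with independently derived
closed forms (Ito isometry, Fubini/lognormal moments) at a 3-standard-error
band; quadrature checks compare against deterministic oracles.
"""

import numpy as np
import pytest
from scipy import integrate, stats

import phyloabc as pa
from phyloabc import sde


def _band(sample, expected_mean, expected_var=None):
    """Assert the sample mean (and optionally variance) sits within 3 SE."""
    n = sample.size
    se_mean = sample.std(ddof=1) / np.sqrt(n)
    assert abs(sample.mean() - expected_mean) < 3 * se_mean + 1e-12
    if expected_var is not None:
        # SE of the sample variance via fourth central moment
        m4 = np.mean((sample - sample.mean()) ** 4)
        se_var = np.sqrt(max(m4 - sample.var() ** 2, 0) / n)
        assert abs(sample.var(ddof=1) - expected_var) < 3 * se_var


class TestSteps:
    def test_bm_no_time_and_no_noise(self, rng):
        assert sde.bm_step(1.7, 2.5, 0.0, rng=rng) == pytest.approx(1.7)
        assert sde.bm_step(1.7, 0.0, 1.0, rng=rng) == pytest.approx(1.7)

    def test_bm_variance(self, rng):
        x = sde.bm_step(np.zeros(100_000), 2.5, 1.0, rng=rng)
        _band(x, 0.0, 6.25)

    def test_bm_negative_time_rejected(self, rng):
        with pytest.raises(ValueError):
            sde.bm_step(0.0, 1.0, -0.5, rng=rng)

    def test_ou_zero_time_and_stationarity(self, rng):
        assert sde.ou_step(3.0, 0.5, 1.0, 1.0, 0.0, rng=rng) == pytest.approx(3.0)
        x = sde.ou_step(np.full(50_000, 3.0), 2.0, 1.0, 0.5, 50.0, rng=rng)
        _band(x, 1.0, 0.25 / 4.0)

    def test_ou_variance_closed_form(self, rng):
        ax, sx, t = 0.125, 2.5, 1.0
        x = sde.ou_step(np.zeros(100_000), ax, 0.0, sx, t, rng=rng)
        _band(x, 0.0, sx ** 2 * (1 - np.exp(-2 * ax * t)) / (2 * ax))

    def test_ou_requires_positive_force(self, rng):
        with pytest.raises(ValueError):
            sde.ou_step(0.0, 0.0, 0.0, 1.0, 1.0, rng=rng)

    def test_y_step_zero_time_and_relaxation(self, rng):
        assert sde.y_step(2.0, 0.0, 0.5, 1.0, 0.0, rng=rng) == pytest.approx(2.0)
        # sigma_y = 0, constant optimum theta* = 5 via a = theta*(1 - e^{-at})
        ay, t = 2.0, 20.0
        a = 5.0 * (1 - np.exp(-ay * t))
        y = sde.y_step(-3.0, a, ay, 0.0, t, rng=rng)
        assert y == pytest.approx(5.0, abs=1e-8)


class TestGbmTimeIntegral:
    def test_deterministic_integrand(self, rng):
        # b = 0: integral of e^{a s} has closed form, Simpson error O(h^4)
        a, t = 0.5, 1.0
        path = sde.sample_bm_path(0.0, 0.0, t, m=100, rng=rng)
        val = sde.gbm_time_integral(a, 0.0, t, path)
        assert val == pytest.approx((np.exp(a * t) - 1) / a, rel=1e-8)

    def test_zero_drift_zero_vol(self, rng):
        path = sde.sample_bm_path(0.0, 0.0, 2.0, m=10, rng=rng)
        assert sde.gbm_time_integral(0.0, 0.0, 2.0, path) == pytest.approx(2.0)

    def test_mean_matches_fubini_lognormal(self, rng):
        # E int exp(a s + b W_s) ds = (e^{(a + b^2/2) t} - 1)/(a + b^2/2)
        a, b, t, n = 0.5, -1.25, 1.0, 10_000
        path = sde.sample_bm_path(np.zeros(n), np.ones(n), t, rng=rng)
        S = sde.gbm_time_integral(a, b, t, path)
        mu = a + b * b / 2
        _band(S, (np.exp(mu * t) - 1) / mu)

    def test_odd_interval_count_rejected(self, rng):
        with pytest.raises(ValueError):
            sde.sample_bm_path(0.0, 1.0, 1.0, m=11, rng=rng)

    def test_wrong_span_rejected(self, rng):
        path = sde.sample_bm_path(0.0, 1.0, 0.5, m=10, rng=rng)
        with pytest.raises(ValueError):
            sde.gbm_time_integral(0.5, 1.0, 1.0, path)


class TestGouTimeIntegral:
    def test_deterministic_path_matches_quadrature(self):
        # sigma_x = 0: OU mean curve; compare against adaptive quadrature
        ay, ax, thx, x0, b3, t = 0.5, 0.8, 1.5, -1.0, -0.4, 1.0
        path = sde.sample_ou_path(x0, ax, thx, 0.0, t, m=200, rng=1)
        val = sde.gou_time_integral(ay, b3, path)
        f = lambda s: np.exp(ay * s + b3 * (thx + np.exp(-ax * s) * (x0 - thx)))
        ref, _ = integrate.quad(f, 0, t, epsabs=1e-12)
        assert val == pytest.approx(ref, abs=1e-6)

    def test_beta3_zero_reduces_to_exponential_integral(self, rng):
        ay, t = 0.7, 1.0
        path = sde.sample_ou_path(0.3, 0.5, 0.0, 2.0, t, rng=rng)
        val = sde.gou_time_integral(ay, 0.0, path)
        assert val == pytest.approx((np.exp(ay * t) - 1) / ay, rel=1e-8)

    def test_grid_doubling_converges(self):
        # same Brownian bridge refinement not required: deterministic check
        ay, ax, thx, x0, b3, t = 0.5, 0.8, 1.5, -1.0, -0.4, 1.0
        v1 = sde.gou_time_integral(
            ay, b3, sde.sample_ou_path(x0, ax, thx, 0.0, t, m=100, rng=1))
        v2 = sde.gou_time_integral(
            ay, b3, sde.sample_ou_path(x0, ax, thx, 0.0, t, m=200, rng=1))
        assert abs(v1 - v2) < 1e-4


class TestATerm:
    def test_zero_time(self):
        mp = sde.ModelParams(alpha_y=0.5, sigma_x=1.0, sigma_y=1.0)
        rp = sde.RegressionParams(1.0, 2.0, -0.5)
        A, xt = sde.a_term("OUGBM", mp, rp, 0.0, 1.3, None)
        assert A == pytest.approx(0.0)
        assert xt == pytest.approx(1.3)

    def test_unknown_model_rejected(self):
        mp = sde.ModelParams(alpha_y=0.5, sigma_x=1.0, sigma_y=1.0)
        rp = sde.RegressionParams(0.0, 1.0)
        with pytest.raises(ValueError):
            sde.a_term("BMBM", mp, rp, 1.0, 0.0, None)

    def test_ougbm_constant_optimum(self, rng):
        # beta3 = 0 collapses the optimum to beta1 + beta2
        ay, t = 0.5, 1.0
        mp = sde.ModelParams(alpha_y=ay, sigma_x=2.5, sigma_y=1.0)
        rp = sde.RegressionParams(0.3, 0.7, 0.0)
        path = sde.sample_bm_path(0.0, 2.5, t, rng=rng)
        A, _ = sde.a_term("OUGBM", mp, rp, t, 0.0, path)
        assert A == pytest.approx((0.3 + 0.7) * (1 - np.exp(-ay * t)), rel=1e-7)

    def test_oubm_mean_and_ito_isometry_variance(self, rng):
        ay, sx, b2, t, n = 0.5, 2.5, 1.0, 1.0, 10_000
        mp = sde.ModelParams(alpha_y=np.full(n, ay), sigma_x=np.full(n, sx),
                             sigma_y=np.ones(n))
        rp = sde.RegressionParams(np.zeros(n), np.full(n, b2))
        path = sde.sample_bm_path(np.zeros(n), np.full(n, sx), t, rng=rng)
        A, xt = sde.a_term("OUBM", mp, rp, t, np.zeros(n), path)
        var = b2 ** 2 * sx ** 2 * (t - 2 * (1 - np.exp(-ay * t)) / ay
                                   + (1 - np.exp(-2 * ay * t)) / (2 * ay))
        _band(A, 0.0, var)
        # x_t from the same path is the BM endpoint
        _band(xt, 0.0, sx ** 2 * t)

    def test_ouou_exact_terms_and_cross_covariance_variance(self, rng):
        # term 1 exact, term 2 exact, term 3 variance including the
        # cross-covariance of the two stochastic integrals
        ay, ax, thx, sx, b1, b2, x0, t = 0.5, 0.125, 0.25, 2.5, 0.2, 0.6, 1.3, 1.0
        n = 20_000
        mp = sde.ModelParams(alpha_y=np.full(n, ay), sigma_x=np.full(n, sx),
                             sigma_y=np.ones(n), alpha_x=np.full(n, ax),
                             theta_x=np.full(n, thx))
        rp = sde.RegressionParams(np.full(n, b1), np.full(n, b2))
        path = sde.sample_ou_path(np.full(n, x0), np.full(n, ax), thx,
                                  np.full(n, sx), t, rng=rng)
        A, _ = sde.a_term("OUOU", mp, rp, t, np.full(n, x0), path)
        term1 = (b1 + b2 * thx) * (1 - np.exp(-ay * t))
        term2 = -ay * b2 * (x0 - thx) * (np.exp(-ay * t) - np.exp(-ax * t)) / (ay - ax)
        c = ay * sx * b2 / (ay - ax)
        var3 = c * c * ((1 - np.exp(-2 * ax * t)) / (2 * ax)
                        + (1 - np.exp(-2 * ay * t)) / (2 * ay)
                        - 2 * (1 - np.exp(-(ax + ay) * t)) / (ax + ay))
        _band(A, term1 + term2, var3)

    def test_ouou_degenerate_rate_limit(self):
        # alpha_y -> alpha_x: term 2 -> +ay b2 (x0 - thx) t e^{-ay t}
        ay, b2, x0, thx, t = 0.5, 0.6, 1.3, 0.25, 1.0
        exact = lambda ax: -ay * b2 * (x0 - thx) * (np.exp(-ay * t) - np.exp(-ax * t)) / (ay - ax)
        limit = ay * b2 * (x0 - thx) * t * np.exp(-ay * t)
        assert exact(ay + 1e-9) == pytest.approx(limit, rel=1e-5)


class TestGammaLimit:
    def test_reciprocal_integral_is_gamma_distributed(self):
        """For the mean-reverting form int e^{-a s + b W_s} ds at large t,
        the reciprocal follows Gamma(2a/b^2, b^2/2)."""
        ay, sx, b3, t, n = 0.5, 2.5, -0.5, 50.0, 5000
        b = b3 * sx
        rng = np.random.default_rng(11)
        chunks = []
        for _ in range(5):
            path = sde.sample_bm_path(np.zeros(n // 5), np.ones(n // 5), t,
                                      m=5000, rng=rng)
            chunks.append(sde.gbm_time_integral(-ay, b, t, path))
        inv = 1.0 / np.concatenate(chunks)
        shape, scale = 2 * ay / b ** 2, b ** 2 / 2
        res = stats.kstest(inv, "gamma", args=(shape, 0, scale))
        assert res.pvalue > 0.01


class TestEulerMaruyamaOracle:
    def test_ougbm_branch_matches_em_cosimulation(self):
        """Path-based OUGBM branch sampling agrees with brute-force
        Euler-Maruyama of the coupled response/covariate SDEs."""
        ay, sx, sy = 0.5, 1.5, 0.8
        b1, b2, b3 = 0.2, 0.8, -0.5
        t, n = 1.0, 10_000
        rng = np.random.default_rng(99)
        # engine samples
        mp = sde.ModelParams(alpha_y=np.full(n, ay), sigma_x=np.full(n, sx),
                             sigma_y=np.full(n, sy))
        rp = sde.RegressionParams(np.full(n, b1), np.full(n, b2), np.full(n, b3))
        path = sde.sample_bm_path(np.zeros(n), np.full(n, sx), t, rng=rng)
        A, _ = sde.a_term("OUGBM", mp, rp, t, np.zeros(n), path)
        y_engine = sde.y_step(np.zeros(n), A, ay, sy, t, rng=rng)
        # EM oracle
        steps = 4000
        dt = t / steps
        x = np.zeros(n)
        y = np.zeros(n)
        for _ in range(steps):
            theta = b1 + b2 * np.exp(b3 * x)
            y = y + ay * (theta - y) * dt + sy * np.sqrt(dt) * rng.standard_normal(n)
            x = x + sx * np.sqrt(dt) * rng.standard_normal(n)
        se = 3 * np.sqrt(y.var() / n + y_engine.var() / n)
        assert abs(y_engine.mean() - y.mean()) < se
        f = stats.levene(y_engine, y)   # robust variance comparison
        assert f.pvalue > 0.001

    def test_ougou_branch_matches_em_cosimulation(self):
        ay, ax, thx, sx, sy = 0.5, 0.8, 0.5, 1.2, 0.6
        b1, b2, b3 = 0.1, 0.9, -0.6
        t, n = 1.0, 10_000
        rng = np.random.default_rng(98)
        mp = sde.ModelParams(alpha_y=np.full(n, ay), sigma_x=np.full(n, sx),
                             sigma_y=np.full(n, sy), alpha_x=np.full(n, ax),
                             theta_x=np.full(n, thx))
        rp = sde.RegressionParams(np.full(n, b1), np.full(n, b2), np.full(n, b3))
        path = sde.sample_ou_path(np.zeros(n), np.full(n, ax), thx,
                                  np.full(n, sx), t, rng=rng)
        A, _ = sde.a_term("OUGOU", mp, rp, t, np.zeros(n), path)
        y_engine = sde.y_step(np.zeros(n), A, ay, sy, t, rng=rng)
        steps = 4000
        dt = t / steps
        x = np.zeros(n)
        y = np.zeros(n)
        for _ in range(steps):
            theta = b1 + b2 * np.exp(b3 * x)
            y = y + ay * (theta - y) * dt + sy * np.sqrt(dt) * rng.standard_normal(n)
            x = x + ax * (thx - x) * dt + sx * np.sqrt(dt) * rng.standard_normal(n)
        se = 3 * np.sqrt(y.var() / n + y_engine.var() / n)
        assert abs(y_engine.mean() - y.mean()) < se
        f = stats.levene(y_engine, y)
        assert f.pvalue > 0.001
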