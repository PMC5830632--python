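import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from batjsdm.gibbs import (GibbsSampler, sample_truncnorm_lower,
                           slice_update_lograte)
from batjsdm.model import ModelSpec, PriorSet

from conftest import make_probit_model_data, make_tiny_joint_data


class TestTruncatedNormal:
    def test_halfnormal_mean(self):
        """E[Z | Y=1, predictor 0] is the half-normal mean sqrt(2/pi)."""
        rng = np.random.default_rng(0)
        draws = sample_truncnorm_lower(rng, np.zeros(100_000))
        assert draws.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)
        assert np.all(draws > 0)

    def test_truncation_bounds_respected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 3, size=1_000_000)
        draws = sample_truncnorm_lower(rng, a)
        assert np.all(draws > a)
        assert np.all(np.isfinite(draws))

    def test_far_tail_is_accurate(self):
        # naive inverse-CDF breaks down by a ~ 8; the log-space sampler
        # must keep the right location (mean of N(0,1)|X>a ~ a + 1/a)
        rng = np.random.default_rng(2)
        a = np.full(50_000, 8.0)
        draws = sample_truncnorm_lower(rng, a)
        assert draws.mean() == pytest.approx(8.0 + 1 / 8.0, abs=0.01)


class TestSliceSampler:
    def test_zero_count_pulls_rate_down(self):
        """Single cell, y=0, g=0, sigma2=1: E[e] matches 1-D quadrature."""
        y = np.array([0.0])
        g = np.array([0.0])
        s2 = np.array([1.0])
        rng = np.random.default_rng(3)
        L = np.array([0.0])
        draws = np.empty(40_000)
        for k in range(draws.size):
            L = slice_update_lograte(rng, L, y, g, s2)
            draws[k] = L[0]
        f = lambda e: np.exp(-np.exp(e) - 0.5 * e ** 2)
        norm = quad(f, -15, 10)[0]
        target = quad(lambda e: e * f(e), -15, 10)[0] / norm
        assert target < 0
        assert draws[2000:].mean() == pytest.approx(target, abs=0.02)

    def test_positive_count_matches_quadrature(self):
        y = np.array([6.0])
        g = np.array([0.5])
        s2 = np.array([0.4])
        rng = np.random.default_rng(4)
        L = np.array([0.0])
        draws = np.empty(40_000)
        for k in range(draws.size):
            L = slice_update_lograte(rng, L, y, g, s2)
            draws[k] = L[0]
        f = lambda l: np.exp(y[0] * l - np.exp(l)
                             - 0.5 * (l - g[0]) ** 2 / s2[0])
        norm = quad(f, -15, 10)[0]
        target = quad(lambda l: l * f(l), -15, 10)[0] / norm
        assert draws[2000:].mean() == pytest.approx(target, abs=0.02)

    def test_vectorized_cells_stay_finite(self):
        rng = np.random.default_rng(5)
        n = 3000
        y = rng.poisson(3.0, n).astype(float)
        g = rng.normal(0, 1, n)
        s2 = rng.uniform(0.2, 1.0, n)
        L = np.zeros(n)
        for _ in range(50):
            L = slice_update_lograte(rng, L, y, g, s2)
            assert np.all(np.isfinite(L))


def _probit_sampler(seed=0, **spec_kw):
    rng = np.random.default_rng(8)
    data, _ = make_probit_model_data(rng)
    kw = dict(n_iter=10, n_burnin=1, thin=1, seed=seed, n_factors=0,
              fix_gamma=np.zeros((2, 1)), fix_V=np.eye(2), fix_rho=0.0,
              fix_sigma2=1.0)
    kw.update(spec_kw)
    return GibbsSampler(data, ModelSpec(**kw))


class TestCoefficientUpdate:
    def test_single_species_matches_gls_closed_form(self):
        """With Z held fixed (rho=0, no factors, V known), the full
        conditional of beta is the ridge/GLS normal: mean
        (X'X + V^-1)^-1 (X'z + V^-1 mu0)."""
        s = _probit_sampler()
        rng = np.random.default_rng(21)
        s.Z = rng.normal(0.0, 1.0, s.Z.shape)   # arbitrary fixed latents
        X = s.data.X
        draws = np.empty((4000, 2))
        for k in range(draws.shape[0]):
            s.update_coefficients(1)
            draws[k] = s.m1.B[:, 0]
        expect = np.linalg.solve(X.T @ X + np.eye(2), X.T @ s.Z[:, 0])
        se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 5 * se + 0.01)

    def test_prior_recovery_without_cells(self):
        """A species with no present cells draws its model-2 coefficients
        from the community prior N(Gamma t, V) when rho=0."""
        rng = np.random.default_rng(9)
        data = make_tiny_joint_data(rng)
        # species 2 never present
        data.Y_occ[:, 2] = 0
        data.cond_mask[:, 2] = False
        data.Y_cond[:, 2] = np.nan
        gamma = np.array([[0.4, -0.2], [0.1, 0.3]])
        spec = ModelSpec(n_iter=10, n_burnin=1, thin=1, seed=0, n_factors=0,
                         fix_gamma=gamma, fix_V=0.3 * np.eye(2), fix_rho=0.0,
                         fix_sigma2=0.5)
        s = GibbsSampler(data, spec)
        draws = np.empty((6000, 2))
        for k in range(draws.shape[0]):
            s.update_coefficients(2)
            draws[k] = s.m2.B[:, 2]
        mu0 = gamma @ data.T[2]
        se = draws.std(axis=0) / np.sqrt(draws.shape[0] / 2)
        assert np.all(np.abs(draws.mean(axis=0) - mu0) < 4 * se + 0.02)
        assert np.allclose(draws.var(axis=0), 0.3, atol=0.05)

    def test_v_draws_symmetric_pd(self):
        rng = np.random.default_rng(10)
        data = make_tiny_joint_data(rng)
        spec = ModelSpec(n_iter=10, n_burnin=1, thin=1, seed=3, n_factors=1)
        s = GibbsSampler(data, spec)
        for _ in range(50):
            s.sweep()
            for V in (s.m1.V, s.m2.V):
                assert np.allclose(V, V.T)
                assert np.linalg.eigvalsh(V).min() > 0


class TestRhoUpdate:
    def test_identity_c_gives_uniform_grid(self):
        """With C = I, W(rho) = I for every rho: the full conditional is
        the uniform prior over the grid."""
        s = _probit_sampler(fix_rho=None,
                            rho_grid=np.linspace(0, 1, 5))
        rng = np.random.default_rng(30)
        s.m1.B = rng.normal(0, 1, s.m1.B.shape)
        counts = np.zeros(5)
        for _ in range(10_000):
            s.update_rho(1)
            counts[np.argmin(np.abs(s.spec.rho_grid - s.m1.rho))] += 1
        assert chisquare(counts).pvalue > 1e-3

    def test_correlated_pair_prefers_high_rho(self):
        """Two species with near-identical coefficients and C12=0.9: the
        rho full conditional concentrates above 0.5."""
        from batjsdm.core_data import ModelData, PhyloCorrelation
        rng = np.random.default_rng(31)
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = np.ones((n, 2), dtype=np.int8)
        data = ModelData(Y_occ=y, Y_cond=np.where(y > 0, 0.0, np.nan),
                         cond_mask=y > 0, X=X, T=np.ones((2, 1)),
                         C=PhyloCorrelation(["a", "b"],
                                            np.array([[1.0, 0.9],
                                                      [0.9, 1.0]])),
                         site_index=np.zeros(n, int), site_ids=["s"],
                         session_ids=[f"v{i}" for i in range(n)],
                         species_ids=["a", "b"], design_columns=("a", "b"))
        spec = ModelSpec(n_iter=10, n_burnin=1, thin=1, seed=0, n_factors=0,
                         fix_gamma=np.zeros((2, 1)), fix_V=np.eye(2),
                         fix_sigma2=1.0)
        s = GibbsSampler(data, spec)
        s.m1.B = np.array([[1.2, 1.25], [-0.8, -0.78]])
        hits = 0
        n_draws = 4000
        for _ in range(n_draws):
            s.update_rho(1)
            hits += s.m1.rho > 0.5
        assert hits / n_draws > 0.5

    def test_draw_always_on_grid(self):
        s = _probit_sampler(fix_rho=None, rho_grid=np.linspace(0, 1, 11))
        for _ in range(200):
            s.update_coefficients(1)
            s.update_rho(1)
            assert np.any(np.isclose(s.spec.rho_grid, s.m1.rho))


class TestFactorUpdate:
    def test_sessions_share_site_scores(self):
        rng = np.random.default_rng(12)
        data = make_tiny_joint_data(rng)
        spec = ModelSpec(n_iter=10, n_burnin=1, thin=1, seed=5, n_factors=2)
        s = GibbsSampler(data, spec)
        for _ in range(5):
            s.sweep()
        eff = s._site_effect(s.m1)
        for site in range(4):
            rows = np.flatnonzero(data.site_index == site)
            assert np.allclose(eff[rows], eff[rows[0]])

    def test_tau_nondecreasing_when_deltas_exceed_one(self):
        rng = np.random.default_rng(13)
        data = make_tiny_joint_data(rng)
        spec = ModelSpec(n_iter=10, n_burnin=1, thin=1, seed=6, n_factors=3)
        s = GibbsSampler(data, spec)
        for _ in range(50):
            s.sweep()
            if np.all(s.m1.delta >= 1.0):
                assert np.all(np.diff(s.m1.tau) >= 0)


class TestOverdispersionUpdate:
    def test_prior_recovery_without_cells(self):
        """sigma_i^2 for a species with no present cells follows its
        inverse-gamma prior (mean rate/(shape-1))."""
        rng = np.random.default_rng(14)
        data = make_tiny_joint_data(rng)
        data.Y_occ[:, 1] = 0
        data.cond_mask[:, 1] = False
        data.Y_cond[:, 1] = np.nan
        pri = PriorSet(sigma2_shape=3.0, sigma2_rate=1.0)
        spec = ModelSpec(n_iter=10, n_burnin=1, thin=1, seed=7, n_factors=0,
                         priors=pri)
        s = GibbsSampler(data, spec)
        draws = np.empty(20_000)
        for k in range(draws.size):
            s.update_overdispersion()
            draws[k] = s.sigma2[1]
        assert draws.mean() == pytest.approx(1.0 / (3.0 - 1.0), rel=0.05)
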