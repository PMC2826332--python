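import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mimosa import (
    FitConfig,
    MixtureFit,
    MixtureParams,
    PairData,
    correlated_density,
    fit_mixture,
    llr_statistic,
    mixture_loglik,
    partition_probabilities,
    permutation_null_llr,
    uncorrelated_density,
)

finite_xy = st.floats(min_value=-5, max_value=5, allow_nan=False)


class TestDensities:
    def test_uncorrelated_at_origin(self):
        assert uncorrelated_density(0.0, 0.0) == pytest.approx(1.0 / (2 * np.pi))

    @settings(deadline=None, derandomize=True)
    @given(finite_xy, finite_xy)
    def test_uncorrelated_symmetric(self, x, y):
        assert uncorrelated_density(x, y) == pytest.approx(
            uncorrelated_density(y, x), rel=1e-12
        )

    def test_alpha_zero_collapses_to_independence(self):
        g = np.linspace(-3, 3, 13)
        xx, yy = np.meshgrid(g, g)
        np.testing.assert_allclose(
            correlated_density(xx, yy, 0.0), uncorrelated_density(xx, yy), atol=1e-14
        )

    def test_matches_bivariate_normal_closed_form(self):
        # the rotation construction equals the unit-variance bivariate
        # normal with correlation rho = -alpha
        val = correlated_density(1.0, 1.0, -0.8)
        ref = stats.multivariate_normal(
            mean=[0, 0], cov=[[1.0, 0.8], [0.8, 1.0]]
        ).pdf([1.0, 1.0])
        assert val == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("alpha", [-0.95, -0.5, 0.0, 0.3, 0.95])
    def test_bivariate_normal_equivalence_grid(self, alpha):
        g = np.linspace(-3, 3, 25)
        xx, yy = np.meshgrid(g, g)
        ref = stats.multivariate_normal(
            mean=[0, 0], cov=[[1.0, -alpha], [-alpha, 1.0]]
        ).pdf(np.dstack([xx, yy]))
        np.testing.assert_allclose(correlated_density(xx, yy, alpha), ref, atol=1e-10)

    @pytest.mark.parametrize("alpha", [-0.9, -0.5, 0.5, 0.9])
    def test_quadrature_normalization_and_marginals(self, alpha):
        g = np.linspace(-8, 8, 801)
        xx, yy = np.meshgrid(g, g)
        dens = correlated_density(xx, yy, alpha)
        dx = g[1] - g[0]
        assert np.trapezoid(np.trapezoid(dens, dx=dx), dx=dx) == pytest.approx(
            1.0, abs=1e-3
        )
        var_x = np.trapezoid(np.trapezoid(dens * xx**2, dx=dx), dx=dx)
        var_y = np.trapezoid(np.trapezoid(dens * yy**2, dx=dx), dx=dx)
        assert var_x == pytest.approx(1.0, abs=1e-3)
        assert var_y == pytest.approx(1.0, abs=1e-3)

    def test_uncorrelated_quadrature(self):
        g = np.linspace(-8, 8, 801)
        xx, yy = np.meshgrid(g, g)
        dx = g[1] - g[0]
        total = np.trapezoid(np.trapezoid(uncorrelated_density(xx, yy), dx=dx), dx=dx)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_degenerate_alpha_rejected(self):
        with pytest.raises(ValueError):
            correlated_density(0.0, 0.0, 1.0)


class TestParams:
    def test_derived_quantities(self):
        p = MixtureParams(0.5, -0.6)
        assert p.sigma_u2 == pytest.approx(0.4)
        assert p.sigma_v2 == pytest.approx(1.6)
        assert p.theta == pytest.approx(np.pi / 4)
        r = p.aspect_ratio
        assert (r**2 - 1) / (r**2 + 1) == pytest.approx(0.6)

    @pytest.mark.parametrize("f,alpha", [(-0.1, 0.0), (1.1, 0.0), (0.5, 1.0)])
    def test_validation(self, f, alpha):
        with pytest.raises(ValueError):
            MixtureParams(f, alpha)


class TestLoglik:
    def test_single_point_pure_uncorrelated(self):
        pair = PairData([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], ["a", "b", "c"])
        ll = mixture_loglik(pair, MixtureParams(1.0, 0.5))
        assert ll == pytest.approx(3 * np.log(1.0 / (2 * np.pi)))

    def test_alpha_zero_f_irrelevant(self):
        rng = np.random.default_rng(0)
        pair = PairData(
            rng.standard_normal(20), rng.standard_normal(20), [str(i) for i in range(20)]
        )
        lls = [mixture_loglik(pair, MixtureParams(f, 0.0)) for f in (0.0, 0.3, 1.0)]
        assert max(lls) - min(lls) < 1e-12

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        pair = PairData(x, y, [str(i) for i in range(10)])
        f, alpha = 0.3, -0.7
        # independent per-point sum via scipy densities
        pu = stats.multivariate_normal([0, 0], np.eye(2)).pdf(np.c_[x, y])
        pc = stats.multivariate_normal(
            [0, 0], [[1.0, 0.7], [0.7, 1.0]]
        ).pdf(np.c_[x, y])
        expected = np.log(f * pu + (1 - f) * pc).sum()
        assert mixture_loglik(pair, MixtureParams(f, alpha)) == pytest.approx(
            expected, abs=1e-10
        )


class TestFit:
    def test_recovery_smoke(self, make_pair):
        hits = 0
        for seed in range(20):
            fit = fit_mixture(make_pair(0.5, 0.8, 300, seed))
            if 0.35 <= fit.params.f <= 0.65 and 0.65 <= abs(fit.params.alpha) <= 0.95:
                hits += 1
        assert hits >= 14

    def test_boundary_recovery_fully_correlated(self):
        # every sample from the correlated component -> f_hat near 0
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(300)
            y = -0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(300)
            x, y = (x - x.mean()) / x.std(), (y - y.mean()) / y.std()
            fit = fit_mixture(PairData(x, y, [str(i) for i in range(300)]))
            if fit.params.f <= 0.15:
                hits += 1
        assert hits >= 9

    def test_null_llr_small(self):
        llrs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pair = PairData(
                rng.standard_normal(100),
                rng.standard_normal(100),
                [str(i) for i in range(100)],
            )
            llrs.append(llr_statistic(fit_mixture(pair)))
        assert np.median(llrs) < 3.0

    def test_loglik_consistency_and_nesting(self, make_pair):
        pair = make_pair(0.5, 0.8, 300, 7)
        fit = fit_mixture(pair)
        assert fit.loglik == pytest.approx(
            mixture_loglik(pair, fit.params), abs=1e-8
        )
        assert fit.loglik >= fit.loglik_null_f0 - 1e-8
        assert fit.converged

    def test_loglik_beats_every_restart_start(self, make_pair):
        pair = make_pair(0.5, 0.8, 200, 3)
        cfg = FitConfig()
        fit = fit_mixture(pair, cfg)
        for f0 in cfg.f_starts:
            for a0 in cfg.alpha_starts:
                assert fit.loglik >= mixture_loglik(pair, MixtureParams(f0, a0)) - 1e-8

    def test_sign_symmetry(self, make_pair):
        pair = make_pair(0.5, 0.8, 300, 11)
        flipped = PairData(pair.x, -pair.y, list(pair.sample_ids))
        a, b = fit_mixture(pair), fit_mixture(flipped)
        assert b.params.alpha == pytest.approx(-a.params.alpha, abs=1e-6)
        assert b.params.f == pytest.approx(a.params.f, abs=1e-6)
        assert b.loglik == pytest.approx(a.loglik, abs=1e-6)

    def test_min_samples_enforced(self):
        pair = PairData([0.1, 0.2, 0.3], [0.3, 0.1, 0.2], ["a", "b", "c"])
        with pytest.raises(ValueError, match="samples"):
            fit_mixture(pair)

    def test_degenerate_flag_on_independent_alpha(self):
        fit = MixtureFit(
            params=MixtureParams(0.5, 0.01),
            loglik=0.0,
            converged=True,
            n_restarts_used=1,
            loglik_null_f0=0.0,
            alpha_null=0.0,
        )
        assert fit.partition_params == fit.params


class TestPartition:
    def test_f_zero_all_correlated(self, make_pair):
        pair = make_pair(0.5, 0.8, 50, 0)
        q = partition_probabilities(pair, MixtureParams(0.0, 0.5)).q
        np.testing.assert_allclose(q, 1.0)

    def test_f_one_none_correlated(self, make_pair):
        pair = make_pair(0.5, 0.8, 50, 0)
        q = partition_probabilities(pair, MixtureParams(1.0, 0.5)).q
        np.testing.assert_allclose(q, 0.0)

    def test_density_ratio_oracle(self):
        pair = PairData([2.0, 0.0, -1.0], [2.0, 0.0, 1.0], ["a", "b", "c"])
        params = MixtureParams(0.5, -0.8)
        q = partition_probabilities(pair, params).q
        pu = uncorrelated_density(pair.x, pair.y)
        pc = correlated_density(pair.x, pair.y, -0.8)
        np.testing.assert_allclose(q, 0.5 * pc / (0.5 * pu + 0.5 * pc), atol=1e-12)
        # (2, 2) lies on the positively correlated long axis
        assert q[0] > 0.5

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=-0.99, max_value=0.99),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_q_bounded(self, f, alpha, seed):
        rng = np.random.default_rng(seed)
        pair = PairData(
            rng.standard_normal(20), rng.standard_normal(20), [str(i) for i in range(20)]
        )
        q = partition_probabilities(pair, MixtureParams(f, alpha)).q
        assert np.all(q >= 0.0) and np.all(q <= 1.0)

    def test_posterior_mean_matches_mixing_fraction(self, make_pair):
        # mean q over generative samples approaches 1 - f
        pair = make_pair(0.4, 0.8, 5000, 123)
        q = partition_probabilities(pair, MixtureParams(0.4, 0.8)).q
        assert q.mean() == pytest.approx(0.6, abs=0.03)


class TestLLR:
    def test_arithmetic(self):
        fit = MixtureFit(
            params=MixtureParams(0.5, 0.5),
            loglik=-10.0,
            converged=True,
            n_restarts_used=1,
            loglik_null_f0=-11.5,
            alpha_null=0.4,
        )
        assert llr_statistic(fit) == pytest.approx(3.0)
        fit.loglik_null_f0 = -10.0
        assert llr_statistic(fit) == pytest.approx(0.0)

    def test_permutation_null(self, make_pair):
        pair = make_pair(0.5, 0.8, 60, 5)
        a = permutation_null_llr(pair, n_perm=5, seed=9)
        b = permutation_null_llr(pair, n_perm=5, seed=9)
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= -1e-8)
        with pytest.raises(ValueError):
            permutation_null_llr(pair, n_perm=0, seed=1)
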