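"""ML fit, casewise scores, polychoric stage and WLS fit."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from lvforest import (
    GRMParameters,
    ItemSpec,
    ModelSpec,
    casewise_scores,
    estimate_polychoric,
    fit_ml_cfa,
    fit_wls,
    fit_wls_from_responses,
    rmsea,
    simulate_responses,
)
from lvforest.polychoric import bvn_cdf, polychoric_from_table, _cell_probs
from lvforest.simulate import sim1_parameters


def numeric_spec(m=5):
    return ModelSpec(items=tuple(ItemSpec(f"x{i}", "numeric") for i in range(m)))


def numeric_params():
    return GRMParameters(
        loadings=[1.0, 0.8, 1.2, 0.6, 1.0],
        thresholds=[None] * 5,
        factor_mean=0.0,
        factor_variance=0.9,
        intercepts=[0.5, 1.0, -0.3, 2.0, 0.0],
        residual_variances=[0.5, 0.8, 1.2, 0.6, 1.0],
    )


@pytest.fixture(scope="module")
def gaussian_fit():
    spec = numeric_spec()
    p = numeric_params()
    rng = np.random.default_rng(7)
    eta = rng.normal(0.0, np.sqrt(p.factor_variance), 50_000)
    y = simulate_responses(spec, p, eta, rng)
    return spec, p, y, fit_ml_cfa(y, spec)


class TestMLFit:
    def test_recovers_generating_parameters(self, gaussian_fit):
        spec, p, y, fit = gaussian_fit
        assert fit.converged and not fit.heywood
        pi, lam, psi, phi = fit.unpack()
        assert np.max(np.abs(pi - [0.5, 1.0, -0.3, 2.0, 0.0])) < 0.05
        assert np.max(np.abs(lam - p.loadings)) < 0.05
        assert np.max(np.abs(psi - [0.5, 0.8, 1.2, 0.6, 1.0])) < 0.05
        assert abs(phi - 0.9) < 0.05

    def test_score_columns_sum_to_zero_at_optimum(self, gaussian_fit):
        spec, p, y, fit = gaussian_fit
        sc = casewise_scores(fit, y)
        assert np.max(np.abs(sc.sum(axis=0))) < y.shape[0] * 1e-6

    def test_loglik_matches_mvn_density_oracle(self, gaussian_fit):
        spec, p, y, fit = gaussian_fit
        mu, Sigma = fit.implied_moments()
        oracle = multivariate_normal(mu, Sigma).logpdf(y).sum()
        assert fit.loglik == pytest.approx(oracle, abs=1e-6 * abs(oracle))

    def test_scores_match_finite_differences(self, gaussian_fit):
        spec, p, y, fit = gaussian_fit
        rows = y[:3]
        sc = casewise_scores(fit, rows)

        def row_loglik(theta, row):
            f2 = type(fit)(
                spec=spec, theta=theta, param_names=fit.param_names,
                loglik=0.0, converged=True, heywood=False, n=1,
            )
            mu, Sigma = f2.implied_moments()
            return multivariate_normal(mu, Sigma).logpdf(row)

        h = 1e-6
        for j in range(3):
            for a in range(fit.k):
                tp, tm = fit.theta.copy(), fit.theta.copy()
                tp[a] += h
                tm[a] -= h
                fd = (row_loglik(tp, rows[j]) - row_loglik(tm, rows[j])) / (2 * h)
                assert sc[j, a] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_duplicated_rows_give_identical_scores(self, gaussian_fit):
        spec, p, y, fit = gaussian_fit
        doubled = np.vstack([y[:5], y[:5]])
        sc = casewise_scores(fit, doubled)
        assert np.allclose(sc[:5], sc[5:])

    def test_too_few_rows_rejected(self, spec57):
        with pytest.raises(ValueError):
            fit_ml_cfa(np.ones((10, 5)), spec57)


class TestPolychoric:
    def test_bvn_cdf_against_scipy(self):
        pts = [(-0.5, 0.3), (1.2, -1.1), (0.0, 0.0), (2.0, 2.0)]
        for rho in (-0.85, -0.3, 0.0, 0.45, 0.95):
            mvn = multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            for h, k in pts:
                assert bvn_cdf(h, k, rho) == pytest.approx(
                    float(mvn.cdf(np.array([h, k]))), abs=5e-7
                )

    def test_binary_balanced_item_threshold_is_zero(self):
        spec = ModelSpec.ordinal(3, 2)
        y = np.array([[1, 1, 1], [2, 2, 2]] * 30, dtype=float)
        stats = estimate_polychoric(y, spec)
        for i in range(3):
            assert stats.tau[i][0] == pytest.approx(0.0, abs=1e-12)

    def test_independent_items_have_near_zero_correlation(self):
        spec = ModelSpec.ordinal(3, 4)
        rng = np.random.default_rng(1)
        y = rng.integers(1, 5, size=(100_000, 3)).astype(float)
        stats = estimate_polychoric(y, spec)
        for v in stats.correlations.values():
            assert abs(v) < 0.02

    def test_pair_estimate_matches_grid_likelihood_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=4000)
        cut_r, cut_c = np.array([-0.4, 0.7]), np.array([0.1, 1.0])
        a = np.digitize(z[:, 0], cut_r)
        b = np.digitize(z[:, 1], cut_c)
        table = np.zeros((3, 3))
        np.add.at(table, (a, b), 1.0)
        rho_hat = polychoric_from_table(table, cut_r, cut_c)
        grid = np.linspace(-0.998, 0.998, 1997)
        cr = np.concatenate([[-np.inf], cut_r, [np.inf]])
        cc = np.concatenate([[-np.inf], cut_c, [np.inf]])
        ll = [np.sum(table * np.log(_cell_probs(cr, cc, r))) for r in grid]
        assert rho_hat == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_empty_categories_are_collapsed(self, spec57, params_r1):
        rng = np.random.default_rng(0)
        eta = rng.normal(
            params_r1.factor_mean, np.sqrt(params_r1.factor_variance), 400
        )
        y = simulate_responses(spec57, params_r1, eta, rng)
        # force item 2 to use only three of its seven categories
        y[:, 1] = np.where(y[:, 1] <= 3, 1.0, np.where(y[:, 1] <= 5, 4.0, 7.0))
        stats = estimate_polychoric(y, spec57)
        assert stats.spec.items[1].n_categories == 3
        assert 1 in stats.collapsed
        assert np.all(np.diff(stats.tau[1]) > 0)


class TestWLS:
    def test_recovers_subgroup_generating_values(self, spec57, params_r1):
        rng = np.random.default_rng(13)
        eta = rng.normal(
            params_r1.factor_mean, np.sqrt(params_r1.factor_variance), 100_000
        )
        y = simulate_responses(spec57, params_r1, eta, rng)
        w = fit_wls_from_responses(y, spec57)
        assert w.converged
        est = w.params
        assert np.max(np.abs(est.loadings - params_r1.loadings)) < 0.05
        for i in range(5):
            assert np.max(np.abs(est.thresholds[i] - params_r1.thresholds[i])) < 0.05
        assert abs(est.factor_mean - params_r1.factor_mean) < 0.05
        assert abs(est.factor_variance - params_r1.factor_variance) < 0.05

    def test_degrees_of_freedom_bookkeeping(self, spec57, small_sample):
        y, _ = small_sample
        stats = estimate_polychoric(y, spec57)
        assert stats.dim == 40  # 30 thresholds + 10 correlations
        w = fit_wls(stats)
        assert w.df == 5  # 40 statistics - 35 free parameters

    def test_wls_agrees_with_ml_on_numeric_items(self):
        spec = numeric_spec()
        p = numeric_params()
        rng = np.random.default_rng(21)
        eta = rng.normal(0.0, np.sqrt(p.factor_variance), 50_000)
        y = simulate_responses(spec, p, eta, rng)
        ml = fit_ml_cfa(y, spec)
        w = fit_wls_from_responses(y, spec)
        assert w.converged
        pi, lam, psi, phi = ml.unpack()
        assert np.max(np.abs(w.params.loadings - lam)) < 0.05
        assert abs(w.params.factor_variance - phi) < 0.05
        for i in range(5):
            assert w.params.intercepts[i] == pytest.approx(pi[i], abs=0.05)
            assert w.params.residual_variances[i] == pytest.approx(psi[i], abs=0.05)

    def test_mixed_items_fit(self):
        spec = ModelSpec(
            items=(
                ItemSpec("o1", "ordinal", 4),
                ItemSpec("x1", "numeric"),
                ItemSpec("o2", "ordinal", 4),
                ItemSpec("o3", "ordinal", 4),
            )
        )
        p = GRMParameters(
            loadings=[1.0, 0.8, 1.2, 0.9],
            thresholds=[[0.0, 0.7, 1.4], None, [-0.3, 0.5, 1.2], [-0.8, 0.1, 0.9]],
            intercepts=[None, 0.5, None, None],
            residual_variances=[None, 0.7, None, None],
            factor_mean=0.3,
            factor_variance=0.8,
        )
        rng = np.random.default_rng(4)
        eta = rng.normal(0.3, np.sqrt(0.8), 30_000)
        y = simulate_responses(spec, p, eta, rng)
        w = fit_wls_from_responses(y, spec)
        assert w.converged and w.df > 0
        assert np.max(np.abs(w.params.loadings - p.loadings)) < 0.07
        assert w.rmsea < 0.02

    def test_objective_not_worse_than_generating_parameters(self, spec57, params_r1, small_sample):
        y, _ = small_sample
        stats = estimate_polychoric(y, spec57)
        w = fit_wls(stats)
        from lvforest.wls import _implied_vector

        s = stats.stat_vector
        wt = np.clip(np.diag(stats.gamma), 1e-10, None)
        f_gen = np.sum((s - _implied_vector(params_r1, stats.spec)) ** 2 / wt)
        assert w.dwls_objective <= f_gen + 1e-8


class TestRMSEA:
    def test_truncation_and_algebra(self):
        assert rmsea(3.0, 5, 100) == 0.0
        assert rmsea(10.0, 5, 100) == pytest.approx(np.sqrt(1 / 100))

    def test_monotone_in_T(self):
        vals = [rmsea(t, 5, 500) for t in np.linspace(0, 50, 40)]
        assert np.all(np.diff(vals) >= 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rmsea(1.0, 0, 100)
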