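"""Graded-response probability machinery, simulation and EBM scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from lvforest import (
    GRMParameters,
    ItemSpec,
    ModelSpec,
    ebm_scores,
    numeric_conditional_mean,
    response_distribution,
    simulate_responses,
)
from lvforest.grm import category_probabilities
from lvforest.simulate import sim1_parameters


def brute_force_pmf(loading, thresholds, eta):
    """Independent oracle: evaluate Phi at every cut and difference."""
    cum = [1.0] + [norm.cdf(loading * eta - t) for t in thresholds] + [0.0]
    return np.array([cum[k] - cum[k + 1] for k in range(len(cum) - 1)])


class TestResponseDistribution:
    def test_single_threshold_at_zero_gives_half_half(self):
        p = GRMParameters(loadings=[1.0, 1.0, 1.0], thresholds=[[0.0], [0.0], [0.0]])
        assert np.allclose(response_distribution(p, 0, 0.0), [0.5, 0.5])

    def test_r1_item1_cumulative_probability_at_own_threshold(self, params_r1):
        # lambda_1 = 1 and the second cut of item 1 sits at 0.31, so at
        # eta = 0.31 the probability of category >= 3 is exactly one half
        pmf = response_distribution(params_r1, 0, 0.31)
        assert pmf[2:].sum() == pytest.approx(0.5, abs=1e-12)

    @given(
        lam=st.floats(-2.0, 2.0),
        eta=st.floats(-4.0, 4.0),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pmf_matches_bruteforce_oracle(self, lam, eta, data):
        k = data.draw(st.integers(2, 7))
        raw = data.draw(
            st.lists(st.floats(-2.5, 2.5), min_size=k - 1, max_size=k - 1, unique=True)
        )
        thresholds = np.sort(np.asarray(raw))
        if np.any(np.diff(thresholds) < 1e-3):
            thresholds = np.cumsum(np.concatenate([[thresholds[0]], np.full(k - 2, 0.5)]))
        pmf = category_probabilities(lam, thresholds, np.array([eta]))[0]
        oracle = brute_force_pmf(lam, thresholds, eta)
        assert np.allclose(pmf, oracle, atol=1e-12)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pmf >= 0)

    def test_cumulative_monotone_in_eta_for_positive_loading(self, params_r1):
        etas = np.linspace(-4, 4, 41)
        for i in range(5):
            pmf = category_probabilities(
                params_r1.loadings[i], params_r1.thresholds[i], etas
            )
            cum_upper = 1.0 - np.cumsum(pmf, axis=1)[:, :-1]  # P(Y >= k+1)
            assert np.all(np.diff(cum_upper, axis=0) >= -1e-12)

    def test_rejects_non_monotone_thresholds(self):
        p = GRMParameters(
            loadings=[1.0, 1.0, 1.0], thresholds=[[0.5, 0.0], [0.0, 1.0], [0.0, 1.0]]
        )
        with pytest.raises(ValueError):
            response_distribution(p, 0, 0.0)

    def test_numeric_item_has_no_distribution(self):
        spec = ModelSpec(
            items=(
                ItemSpec("a", "numeric"),
                ItemSpec("b", "ordinal", 3),
                ItemSpec("c", "ordinal", 3),
            )
        )
        p = GRMParameters(
            loadings=[1.0, 0.5, 0.5],
            thresholds=[None, [0.0, 1.0], [0.0, 1.0]],
            intercepts=[0.0, None, None],
            residual_variances=[1.0, None, None],
        )
        with pytest.raises(ValueError):
            response_distribution(p, 0, 0.0, spec=spec)
        assert numeric_conditional_mean(p, 0, 4.0, spec=spec) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            numeric_conditional_mean(p, 1, 0.0, spec=spec)

    @pytest.mark.parametrize("pi,lam,eta", [(0.0, 1.0, 0.0), (2.0, 0.5, 4.0), (-1.5, 1.3, 0.7)])
    def test_numeric_conditional_mean_is_affine(self, pi, lam, eta):
        spec = ModelSpec(
            items=(ItemSpec("a", "numeric"), ItemSpec("b", "numeric"), ItemSpec("c", "numeric"))
        )
        p = GRMParameters(
            loadings=[lam, 1.0, 1.0],
            thresholds=[None] * 3,
            intercepts=[pi, 0.0, 0.0],
            residual_variances=[1.0, 1.0, 1.0],
        )
        assert numeric_conditional_mean(p, 0, eta) == pytest.approx(pi + lam * eta)


class TestSimulateResponses:
    def test_degenerate_thresholds_yield_single_category(self, spec57):
        thr = [np.array([-30.0, -29, -28, -27, -26, -25])] * 5  # all mass in category 7
        p = GRMParameters(loadings=np.ones(5), thresholds=thr)
        y = simulate_responses(spec57, p, np.zeros(50), np.random.default_rng(0))
        assert np.all(y == 7)

    def test_support_and_reproducibility(self, spec57, params_r1):
        rng = np.random.default_rng(11)
        eta = rng.normal(size=300)
        y1 = simulate_responses(spec57, params_r1, eta, np.random.default_rng(5))
        y2 = simulate_responses(spec57, params_r1, eta, np.random.default_rng(5))
        assert np.array_equal(y1, y2)
        assert y1.min() >= 1 and y1.max() <= 7

    def test_empirical_frequencies_match_pmf(self, spec57, params_r1):
        n = 200_000
        eta = np.full(n, 0.7)
        y = simulate_responses(spec57, params_r1, eta, np.random.default_rng(3))
        for i in range(5):
            freq = np.bincount(y[:, i].astype(int), minlength=8)[1:] / n
            pmf = response_distribution(params_r1, i, 0.7)
            assert np.max(np.abs(freq - pmf)) < 0.01


class TestEBMScores:
    def grid_oracle(self, spec, params, row, n_grid=200_001):
        mu, sd = params.factor_mean, np.sqrt(params.factor_variance)
        g = np.linspace(mu - 6 * sd, mu + 6 * sd, n_grid)
        lp = -0.5 * (g - mu) ** 2 / params.factor_variance
        for i in range(spec.n_items):
            pmf = category_probabilities(params.loadings[i], params.thresholds[i], g)
            lp += np.log(np.clip(pmf[np.arange(g.size), int(row[i]) - 1], 1e-300, None))
        return g[np.argmax(lp)]

    def test_zero_loadings_return_prior_mean(self):
        spec = ModelSpec.ordinal(3, 3)
        p = GRMParameters(
            loadings=[1.0, 0.0, 0.0],
            thresholds=[[0.0, 1.0]] * 3,
            factor_mean=0.4,
            factor_variance=1.2,
        )
        p.loadings = np.zeros(3)  # flat likelihood in eta
        y = np.array([[1, 2, 3], [3, 3, 3]])
        s = ebm_scores(spec, p, y)
        assert np.allclose(s.values, 0.4)

    @pytest.mark.parametrize("h", [0, 4, 7])
    def test_mode_matches_grid_search_oracle(self, h, spec57):
        params = sim1_parameters(h)
        rng = np.random.default_rng(h)
        eta = rng.normal(params.factor_mean, np.sqrt(params.factor_variance), 40)
        y = simulate_responses(spec57, params, eta, rng)
        s = ebm_scores(spec57, params, y)
        assert s.available.all()
        for j in range(0, 40, 7):
            assert s.values[j] == pytest.approx(
                self.grid_oracle(spec57, params, y[j]), abs=1e-4
            )

    def test_mixed_numeric_and_ordinal_mode(self):
        spec = ModelSpec(
            items=(
                ItemSpec("o1", "ordinal", 4),
                ItemSpec("x1", "numeric"),
                ItemSpec("o2", "ordinal", 4),
            )
        )
        p = GRMParameters(
            loadings=[1.0, 0.8, 1.2],
            thresholds=[[-0.5, 0.3, 1.1], None, [0.0, 0.8, 1.6]],
            intercepts=[None, 0.5, None],
            residual_variances=[None, 0.7, None],
            factor_mean=0.2,
            factor_variance=0.9,
        )
        rng = np.random.default_rng(8)
        eta = rng.normal(0.2, np.sqrt(0.9), 200)
        y = simulate_responses(spec, p, eta, rng)
        s = ebm_scores(spec, p, y)
        # oracle by dense grid on the mixed posterior
        mu, sd = 0.2, np.sqrt(0.9)
        g = np.linspace(mu - 6 * sd, mu + 6 * sd, 120_001)
        for j in (0, 50, 199):
            lp = -0.5 * (g - mu) ** 2 / 0.9
            for i, item in enumerate(spec.items):
                if item.is_ordinal:
                    pmf = category_probabilities(p.loadings[i], p.thresholds[i], g)
                    lp += np.log(np.clip(pmf[np.arange(g.size), int(y[j, i]) - 1], 1e-300, None))
                else:
                    lp += -0.5 * (y[j, i] - p.intercepts[i] - p.loadings[i] * g) ** 2 / p.residual_variances[i]
            assert s.values[j] == pytest.approx(g[np.argmax(lp)], abs=1e-4)

    def test_higher_category_never_decreases_score(self):
        """Monotone likelihood ratio: with positive loadings, moving one item
        up a category can only move the posterior mode up.  Checked
        exhaustively on a 3-item, 3-category model."""
        spec = ModelSpec.ordinal(3, 3)
        p = GRMParameters(
            loadings=[1.0, 0.7, 1.3],
            thresholds=[[0.0, 0.9], [-0.4, 0.6], [0.2, 1.4]],
            factor_mean=0.1,
            factor_variance=0.8,
        )
        patterns = np.array(
            [[a, b, c] for a in (1, 2, 3) for b in (1, 2, 3) for c in (1, 2, 3)]
        )
        s = ebm_scores(spec, p, patterns.astype(float)).values
        score = {tuple(row): v for row, v in zip(patterns, s)}
        for row in patterns:
            for i in range(3):
                if row[i] < 3:
                    up = row.copy()
                    up[i] += 1
                    assert score[tuple(up)] >= score[tuple(row)] - 1e-8


class TestParameterContainers:
    def test_json_round_trip(self, params_r1):
        restored = GRMParameters.from_json(params_r1.to_json())
        assert np.allclose(restored.loadings, params_r1.loadings)
        for a, b in zip(restored.thresholds, params_r1.thresholds):
            assert np.allclose(a, b)
        assert restored.factor_mean == params_r1.factor_mean

    def test_validation_rejects_bad_parameters(self, spec57, params_r1):
        bad = GRMParameters.from_dict(params_r1.to_dict())
        bad.loadings[0] = 2.0  # reference loading must stay fixed at 1
        with pytest.raises(ValueError):
            bad.validate(spec57)
        bad2 = GRMParameters.from_dict(params_r1.to_dict())
        bad2.factor_variance = -1.0
        with pytest.raises(ValueError):
            bad2.validate(spec57)

    def test_model_spec_invariants(self):
        with pytest.raises(ValueError):
            ModelSpec.ordinal(2, 5)  # fewer than 3 items
        with pytest.raises(ValueError):
            ItemSpec("x", "ordinal", 1)  # fewer than 2 categories
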