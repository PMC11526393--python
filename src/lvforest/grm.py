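"""Probability machinery, response simulation and empirical-Bayes-modal scoring.

All category codes at the API boundary are 1-based (a 7-point item takes values
1..7); internal arrays are 0-based.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

from .model import GRMParameters, LatentScores, ModelSpec

__all__ = [
    "response_distribution",
    "numeric_conditional_mean",
    "simulate_responses",
    "ebm_scores",
]


def _check_ordinal(spec: ModelSpec, item: int) -> None:
    if not spec.items[item].is_ordinal:
        raise ValueError(f"item {spec.items[item].name!r} is not ordinal")


def category_probabilities(
    loading: float, thresholds: np.ndarray, eta: np.ndarray
) -> np.ndarray:
    """Category pmf matrix (len(eta), K) from the cumulative probit curves.

    P(Y >= k | eta) = Phi(loading * eta - thresholds[k-2]) for k = 2..K, and the
    pmf is obtained by differencing adjacent cumulative probabilities.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    # cum[:, k] = P(Y >= k+1 | eta); cum[:, 0] = 1 by convention.
    upper = ndtr(loading * eta[:, None] - thresholds[None, :])
    cum = np.concatenate(
        [np.ones((eta.size, 1)), upper, np.zeros((eta.size, 1))], axis=1
    )
    pmf = cum[:, :-1] - cum[:, 1:]
    return np.clip(pmf, 0.0, 1.0)


def response_distribution(
    params: GRMParameters, item: int, eta: float, spec: Optional[ModelSpec] = None
) -> np.ndarray:
    """Probability vector over the categories of one ordinal item at a given eta."""
    if spec is not None:
        _check_ordinal(spec, item)
    thresholds = params.thresholds[item]
    if thresholds is None:
        raise ValueError("item has no thresholds; not an ordinal item")
    if not np.isfinite(eta):
        raise ValueError("eta must be finite")
    return category_probabilities(params.loadings[item], thresholds, eta)[0]


def numeric_conditional_mean(
    params: GRMParameters, item: int, eta: float, spec: Optional[ModelSpec] = None
) -> float:
    """Conditional mean pi_i + lambda_i * eta of a numeric item."""
    if spec is not None and spec.items[item].is_ordinal:
        raise ValueError(f"item {spec.items[item].name!r} is ordinal, not numeric")
    pi = params.intercepts[item]
    if pi is None:
        raise ValueError("item has no intercept; not a numeric item")
    return float(pi + params.loadings[item] * eta)


def simulate_responses(
    spec: ModelSpec,
    params: GRMParameters,
    etas: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a response matrix (n, m) given latent values.

    Ordinal cells are drawn from the graded-response pmf at each row's eta
    (returned as 1-based category codes); numeric cells are Gaussian around the
    conditional mean.
    """
    params.validate(spec)
    etas = np.asarray(etas, dtype=float)
    if not np.all(np.isfinite(etas)):
        raise ValueError("etas must be finite")
    n, m = etas.size, spec.n_items
    out = np.empty((n, m), dtype=float)
    for i, item in enumerate(spec.items):
        if item.is_ordinal:
            pmf = category_probabilities(params.loadings[i], params.thresholds[i], etas)
            cdf = np.cumsum(pmf, axis=1)
            cdf[:, -1] = 1.0
            u = rng.random(n)
            out[:, i] = 1 + np.sum(u[:, None] > cdf[:, :-1], axis=1)
        else:
            mean = params.intercepts[i] + params.loadings[i] * etas
            out[:, i] = mean + rng.normal(0.0, np.sqrt(params.residual_variances[i]), n)
    return out


def _log_posterior_terms(
    spec: ModelSpec, params: GRMParameters, eta_grid: np.ndarray
) -> list[np.ndarray]:
    """Per-item log-probability tables over the eta grid.

    For ordinal item i the table has shape (K_i, G); numeric items are handled
    separately because their contribution depends on the observed value.
    """
    tables = []
    for i, item in enumerate(spec.items):
        if item.is_ordinal:
            pmf = category_probabilities(
                params.loadings[i], params.thresholds[i], eta_grid
            ).T  # (K, G)
            with np.errstate(divide="ignore"):
                tables.append(np.log(pmf))
        else:
            tables.append(None)
    return tables


def _posterior_derivatives(
    spec: ModelSpec,
    params: GRMParameters,
    responses: np.ndarray,
    eta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivative of the log posterior at each pattern's eta."""
    mu, phi = params.factor_mean, params.factor_variance
    d1 = -(eta - mu) / phi
    d2 = np.full_like(eta, -1.0 / phi)
    tiny = 1e-300
    for i, item in enumerate(spec.items):
        lam = params.loadings[i]
        if item.is_ordinal:
            kappa = params.thresholds[i]
            k = responses[:, i].astype(int) - 1  # 0-based category
            # z bounds: upper cut for category k is kappa[k-1] (z_low side), see pmf
            # P(Y=k) = Phi(lam*eta - kappa[k-1]) - Phi(lam*eta - kappa[k])
            z_hi = np.where(k > 0, lam * eta - kappa[np.maximum(k - 1, 0)], np.inf)
            z_lo = np.where(
                k < kappa.size, lam * eta - kappa[np.minimum(k, kappa.size - 1)], -np.inf
            )
            F = ndtr(np.where(np.isfinite(z_hi), z_hi, 40.0)) - ndtr(
                np.where(np.isfinite(z_lo), z_lo, -40.0)
            )
            _c = 1.0 / np.sqrt(2.0 * np.pi)
            f_hi = np.where(np.isfinite(z_hi), _c * np.exp(-0.5 * np.where(np.isfinite(z_hi), z_hi, 0.0) ** 2), 0.0)
            f_lo = np.where(np.isfinite(z_lo), _c * np.exp(-0.5 * np.where(np.isfinite(z_lo), z_lo, 0.0) ** 2), 0.0)
            df = f_hi - f_lo  # d/d(lam*eta) of F
            # d2/d(lam*eta)^2 of F: -z*pdf(z) differenced (z replaced where pdf is 0)
            zh = np.where(np.isfinite(z_hi), z_hi, 0.0)
            zl = np.where(np.isfinite(z_lo), z_lo, 0.0)
            ddf = -zh * f_hi + zl * f_lo
            F = np.maximum(F, tiny)
            r1 = np.clip(df / F, -1e12, 1e12)
            r2 = np.clip(ddf / F, -1e12, 1e12)
            d1 += lam * r1
            d2 += lam**2 * (r2 - r1**2)
        else:
            psi = params.residual_variances[i]
            resid = responses[:, i] - params.intercepts[i] - lam * eta
            d1 += lam * resid / psi
            d2 += -(lam**2) / psi
    return d1, d2


def ebm_scores(
    spec: ModelSpec,
    params: GRMParameters,
    responses: np.ndarray,
    grid_size: int = 201,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> LatentScores:
    """Empirical Bayes modal scores: the posterior mode of eta per response row.

    The posterior combines the normal prior N(factor_mean, factor_variance) with
    the item likelihoods.  The mode is located on a grid spanning +-8 prior SDs
    and polished with damped Newton steps; the posterior is log-concave, so the
    grid maximizer is in the basin of the global mode.  Rows with identical
    response patterns share one optimization.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 2 or responses.shape[1] != spec.n_items:
        raise ValueError("response matrix does not match the model spec")
    n = responses.shape[0]
    if n == 0:
        return LatentScores(np.empty(0), np.empty(0, dtype=bool))

    mu, phi = params.factor_mean, params.factor_variance
    sd = np.sqrt(phi)
    if np.allclose(params.loadings, 0.0):
        # likelihood flat in eta: the posterior mode is the prior mean
        return LatentScores(np.full(n, mu), np.ones(n, dtype=bool))
    params.validate(spec)

    patterns, inverse = np.unique(responses, axis=0, return_inverse=True)
    P = patterns.shape[0]
    lo, hi = mu - 8.0 * sd, mu + 8.0 * sd
    grid = np.linspace(lo, hi, grid_size)

    logp = np.tile(-0.5 * (grid - mu) ** 2 / phi, (P, 1))  # (P, G)
    tables = _log_posterior_terms(spec, params, grid)
    for i, item in enumerate(spec.items):
        if item.is_ordinal:
            codes = patterns[:, i].astype(int) - 1
            logp += tables[i][codes, :]
        else:
            lam, pi, psi = params.loadings[i], params.intercepts[i], params.residual_variances[i]
            resid = patterns[:, i][:, None] - pi - lam * grid[None, :]
            logp += -0.5 * resid**2 / psi

    eta = grid[np.argmax(logp, axis=1)]
    step_cap = 2.0 * (grid[1] - grid[0])
    converged = np.zeros(P, dtype=bool)
    for _ in range(max_iter):
        d1, d2 = _posterior_derivatives(spec, params, patterns, eta)
        active = ~converged
        if not np.any(active):
            break
        step = np.where(d2 < -1e-12, -d1 / d2, np.sign(d1) * step_cap)
        step = np.clip(step, -step_cap, step_cap)
        eta_new = np.clip(eta + np.where(active, step, 0.0), lo, hi)
        converged |= np.abs(eta_new - eta) < tol
        eta = eta_new
    # Flag non-finite results (should not occur for valid parameters)
    ok = np.isfinite(eta)
    values = np.where(ok, eta, np.nan)[inverse]
    return LatentScores(values, ok[inverse])
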