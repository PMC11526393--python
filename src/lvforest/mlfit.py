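"""Normal-theory maximum-likelihood fit of the one-factor model.

During tree growth the items — including ordinal ones, coded 1..K — are treated
as jointly Gaussian with mean ``mu(theta) = pi`` and covariance
``Sigma(theta) = phi * lambda lambda' + diag(psi)``.  This is deliberately a
working model: it supplies the casewise score functions that drive the
parameter-instability tests cheaply, while terminal nodes are later re-fit with
the limited-information WLS estimator that respects the ordinal scale.

Identification: the reference loading is fixed to 1, the factor mean to 0, all
intercepts and residual variances and the factor variance are free, giving
``k = 3m`` parameters for ``m`` items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import ModelSpec

__all__ = ["MLFitResult", "fit_ml_cfa", "casewise_scores"]

_VAR_FLOOR = 1e-6


@dataclass
class MLFitResult:
    """ML estimate of the Gaussian one-factor model.

    ``theta`` stacks (intercepts pi_1..pi_m, free loadings in item order,
    residual variances psi_1..psi_m, factor variance phi); ``param_names``
    matches.  ``info`` is the outer-product-of-gradients information estimate
    (the sample covariance of the casewise scores), used to scale the
    fluctuation process.
    """

    spec: ModelSpec
    theta: np.ndarray
    param_names: list[str]
    loglik: float
    converged: bool
    heywood: bool
    n: int
    info: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.theta.size

    def unpack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Return (pi, lambda, psi, phi) with the reference loading restored."""
        m = self.spec.n_items
        ref = self.spec.reference_item
        pi = self.theta[:m]
        lam = np.empty(m)
        free = [i for i in range(m) if i != ref]
        lam[ref] = 1.0
        lam[free] = self.theta[m : 2 * m - 1]
        psi = self.theta[2 * m - 1 : 3 * m - 1]
        phi = self.theta[-1]
        return pi, lam, psi, phi

    def implied_moments(self) -> tuple[np.ndarray, np.ndarray]:
        pi, lam, psi, phi = self.unpack()
        return pi, phi * np.outer(lam, lam) + np.diag(psi)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "param_names": self.param_names,
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "heywood": bool(self.heywood),
            "n": int(self.n),
        }


def _param_names(spec: ModelSpec) -> list[str]:
    names = [f"pi[{it.name}]" for it in spec.items]
    names += [
        f"lambda[{it.name}]"
        for i, it in enumerate(spec.items)
        if i != spec.reference_item
    ]
    names += [f"psi[{it.name}]" for it in spec.items]
    names.append("phi")
    return names


def _neg_loglik_and_grad(
    theta: np.ndarray, spec: ModelSpec, ybar: np.ndarray, S: np.ndarray, n: int
):
    m = spec.n_items
    ref = spec.reference_item
    free = [i for i in range(m) if i != ref]
    pi = theta[:m]
    lam = np.empty(m)
    lam[ref] = 1.0
    lam[free] = theta[m : 2 * m - 1]
    psi = theta[2 * m - 1 : 3 * m - 1]
    phi = theta[-1]

    Sigma = phi * np.outer(lam, lam) + np.diag(psi)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Sinv = np.linalg.inv(Sigma)
    d = ybar - pi
    quad = float(d @ Sinv @ d)
    trace = float(np.sum(Sinv * S))
    ll = -0.5 * n * (m * np.log(2 * np.pi) + logdet + trace + quad)

    # Gradient of ll via A = Sinv (S + dd') Sinv - Sinv
    A = Sinv @ (S + np.outer(d, d)) @ Sinv - Sinv
    g_pi = n * (Sinv @ d)
    Al = A @ lam
    g_lam = n * phi * Al[free]
    g_psi = 0.5 * n * np.diag(A)
    g_phi = 0.5 * n * float(lam @ Al)
    grad = np.concatenate([g_pi, g_lam, g_psi, [g_phi]])
    return -ll, -grad


def _start_values(spec: ModelSpec, ybar: np.ndarray, S: np.ndarray) -> np.ndarray:
    m = spec.n_items
    ref = spec.reference_item
    others = [i for i in range(m) if i != ref]
    # Triad start for phi using the two strongest companions of the reference item
    cov = S[ref, others]
    order = np.argsort(-np.abs(cov))
    phi0 = 0.5 * S[ref, ref]
    if m >= 3:
        a, b = others[order[0]], others[order[1]]
        if abs(S[a, b]) > 1e-10:
            cand = S[ref, a] * S[ref, b] / S[a, b]
            if np.isfinite(cand) and cand > 1e-4:
                phi0 = min(cand, 0.95 * S[ref, ref])
    lam0 = np.ones(m)
    lam0[others] = S[ref, others] / phi0
    lam0 = np.clip(lam0, -5.0, 5.0)
    psi0 = np.maximum(np.diag(S) - lam0**2 * phi0, 0.1 * np.diag(S))
    theta0 = np.concatenate([ybar, lam0[others], psi0, [phi0]])
    return theta0


def fit_ml_cfa(responses: np.ndarray, spec: ModelSpec) -> MLFitResult:
    """Fit the Gaussian one-factor model by ML; all items treated as numeric."""
    y = np.asarray(responses, dtype=float)
    n, m = y.shape
    if m != spec.n_items:
        raise ValueError("response matrix does not match the model spec")
    if n < 3 * m:
        raise ValueError(f"need at least {3 * m} rows to fit {3 * m} parameters")
    ybar = y.mean(axis=0)
    yc = y - ybar
    S = yc.T @ yc / n

    theta0 = _start_values(spec, ybar, S)
    k = theta0.size
    bounds = (
        [(None, None)] * m
        + [(None, None)] * (m - 1)
        + [(_VAR_FLOOR, None)] * m
        + [(_VAR_FLOOR, None)]
    )
    res = minimize(
        _neg_loglik_and_grad,
        theta0,
        args=(spec, ybar, S, n),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = res.x
    psi = theta[2 * m - 1 : 3 * m - 1]
    heywood = bool(np.any(psi <= 2 * _VAR_FLOOR) or theta[-1] <= 2 * _VAR_FLOOR)
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, n)
    converged = bool(res.success and np.isfinite(res.fun)) and grad_ok
    fit = MLFitResult(
        spec=spec,
        theta=theta,
        param_names=_param_names(spec),
        loglik=-float(res.fun),
        converged=converged,
        heywood=heywood,
        n=n,
    )
    if converged:
        scores = casewise_scores(fit, y)
        fit.info = scores.T @ scores / n
    return fit


def casewise_scores(fit: MLFitResult, responses: np.ndarray) -> np.ndarray:
    """Row-wise gradient of the Gaussian log-density at the fitted parameters.

    Returns an (n, k) matrix whose columns sum to ~0 at the ML optimum.
    """
    if not fit.converged:
        raise ValueError("casewise scores require a converged fit")
    y = np.asarray(responses, dtype=float)
    spec = fit.spec
    m = spec.n_items
    ref = spec.reference_item
    free = [i for i in range(m) if i != ref]
    pi, lam, psi, phi = fit.unpack()
    Sigma = phi * np.outer(lam, lam) + np.diag(psi)
    Sinv = np.linalg.inv(Sigma)

    r = y - pi  # (n, m)
    u = r @ Sinv  # (n, m) rows: Sinv (y_j - pi)
    # A_j = u_j u_j' - Sinv;  needed contractions only.
    s_pi = u
    ul = u @ lam  # (n,)
    sl = Sinv @ lam
    # (A_j lam)_i = u_ji * (u_j . lam) - (Sinv lam)_i
    Alam = u * ul[:, None] - sl[None, :]
    s_lam = phi * Alam[:, free]
    s_psi = 0.5 * (u**2 - np.diag(Sinv)[None, :])
    s_phi = 0.5 * (ul**2 - float(lam @ sl))
    return np.concatenate([s_pi, s_lam, s_psi, s_phi[:, None]], axis=1)
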