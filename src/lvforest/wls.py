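"""Diagonally weighted least squares fit of the one-factor model to
limited-information statistics, with a full-weight chi-square and RMSEA.

The model is parameterized in conditional-probit (theta) form: each ordinal
item's latent response has unit residual variance, so the free parameters are
the thresholds ``kappa`` (first threshold of the first ordinal item fixed to 0),
the loadings (reference fixed to 1), the factor mean and variance, and —
for numeric items — intercepts and residual variances.  The model-implied
marginal statistics are

    tau_ik   = (kappa_ik - lambda_i mu) / s_i,        s_i = sqrt(lambda_i^2 phi + 1)
    rho_ij   = lambda_i lambda_j phi / (s_i s_j)
    mean_i   = pi_i + lambda_i mu                      (numeric)
    var_i    = lambda_i^2 phi + psi_i                  (numeric)

with ``s_i`` replaced by the model SD for numeric items in mixed correlations.
Estimation minimizes the discrepancy weighted by the inverse diagonal of the
asymptotic covariance (DWLS).  The reported test statistic is the
mean-and-variance-adjusted (scaled-shifted) DWLS chi-square: the raw quadratic
form T_d = n (s - sigma)' W_d^{-1} (s - sigma) is an eigenvalue mixture of
chi-squares under a correct model, so it is rescaled as a T_d + b with a, b
chosen from the residual-weight operator U = W_d^{-1} - W_d^{-1} Delta
(Delta' W_d^{-1} Delta)^{-1} Delta' W_d^{-1} so that T has mean df and
variance 2 df under the model — the standard, well-calibrated default for
DWLS-estimated ordinal factor models at moderate n.  RMSEA uses this T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .grm import ebm_scores
from .model import GRMParameters, LatentScores, ModelSpec
from .polychoric import PolychoricStats, estimate_polychoric

__all__ = ["WLSFitResult", "fit_wls", "fit_wls_from_responses", "rmsea", "score_with_wls"]

logger = logging.getLogger(__name__)


def rmsea(T: float, df: int, n: int) -> float:
    """Root mean square error of approximation, population-discrepancy form."""
    if df <= 0 or n <= 0:
        raise ValueError("df and n must be positive")
    return float(np.sqrt(max(0.0, (T - df) / (df * n))))


@dataclass
class WLSFitResult:
    """DWLS parameter estimates plus fit statistics for one subgroup sample."""

    spec: ModelSpec  # effective spec (collapsed categories)
    params: GRMParameters
    T: float
    df: int
    rmsea: float
    converged: bool
    n: int
    collapsed: dict[int, np.ndarray]
    dwls_objective: float = np.nan

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "T": float(self.T),
            "df": int(self.df),
            "rmsea": float(self.rmsea),
            "converged": bool(self.converged),
            "n": int(self.n),
        }


class _ParamMap:
    """Bookkeeping between the flat optimization vector and model quantities."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        m = spec.n_items
        ord_idx = spec.ordinal_indices
        self.anchor_item = ord_idx[0] if ord_idx else None
        self.mu_free = self.anchor_item is not None
        slices: dict[str, object] = {}
        pos = 0
        self.kappa_slices: dict[int, tuple[int, int, bool]] = {}
        for i in ord_idx:
            K = spec.items[i].n_categories
            fixed_first = i == self.anchor_item
            nfree = K - 1 - (1 if fixed_first else 0)
            self.kappa_slices[i] = (pos, pos + nfree, fixed_first)
            pos += nfree
        self.lam_idx = [i for i in range(m) if i != spec.reference_item]
        self.lam_slice = (pos, pos + len(self.lam_idx))
        pos += len(self.lam_idx)
        self.num_idx = spec.numeric_indices
        self.pi_slice = (pos, pos + len(self.num_idx))
        pos += len(self.num_idx)
        self.logpsi_slice = (pos, pos + len(self.num_idx))
        pos += len(self.num_idx)
        if self.mu_free:
            self.mu_pos = pos
            pos += 1
        self.logphi_pos = pos
        pos += 1
        self.n_free = pos

    def unpack(self, x: np.ndarray) -> GRMParameters:
        spec = self.spec
        m = spec.n_items
        lam = np.ones(m)
        lam[self.lam_idx] = x[self.lam_slice[0] : self.lam_slice[1]]
        thresholds: list = [None] * m
        for i, (a, b, fixed_first) in self.kappa_slices.items():
            vals = x[a:b]
            thresholds[i] = np.concatenate([[0.0], vals]) if fixed_first else vals
        intercepts = [None] * m
        resid = [None] * m
        for slot, i in enumerate(self.num_idx):
            intercepts[i] = float(x[self.pi_slice[0] + slot])
            resid[i] = float(np.exp(x[self.logpsi_slice[0] + slot]))
        mu = float(x[self.mu_pos]) if self.mu_free else 0.0
        phi = float(np.exp(x[self.logphi_pos]))
        return GRMParameters(
            loadings=lam,
            thresholds=thresholds,
            factor_mean=mu,
            factor_variance=phi,
            intercepts=intercepts,
            residual_variances=resid,
        )


def _implied_vector(params: GRMParameters, spec: ModelSpec) -> np.ndarray:
    m = spec.n_items
    lam = params.loadings
    phi = params.factor_variance
    mu = params.factor_mean
    sd = np.empty(m)
    for i, item in enumerate(spec.items):
        if item.is_ordinal:
            sd[i] = np.sqrt(lam[i] ** 2 * phi + 1.0)
        else:
            sd[i] = np.sqrt(lam[i] ** 2 * phi + params.residual_variances[i])
    vals: list[float] = []
    for i, item in enumerate(spec.items):
        if item.is_ordinal:
            vals.extend(((params.thresholds[i] - lam[i] * mu) / sd[i]).tolist())
        else:
            vals.append(params.intercepts[i] + lam[i] * mu)
            vals.append(sd[i] ** 2)
    for i in range(m):
        for j in range(i + 1, m):
            vals.append(lam[i] * lam[j] * phi / (sd[i] * sd[j]))
    return np.asarray(vals)


def _principal_factor_loadings(R: np.ndarray, ref: int, n_iter: int = 25) -> np.ndarray:
    """Standardized loadings of a one-factor solution by iterated principal factors."""
    m = R.shape[0]
    Rw = R.copy()
    h = np.clip(1.0 - 1.0 / np.maximum(np.diag(np.linalg.pinv(R)), 1.0 + 1e-6), 0.1, 0.9)
    l = None
    for _ in range(n_iter):
        np.fill_diagonal(Rw, h)
        w, v = np.linalg.eigh(Rw)
        e1 = max(w[-1], 1e-6)
        l = np.sqrt(e1) * v[:, -1]
        h = np.clip(l**2, 0.01, 0.96)
    if l[ref] < 0:
        l = -l
    return np.clip(l, -0.98, 0.98)


def _start_vector(stats: PolychoricStats, pm: _ParamMap) -> np.ndarray:
    spec = stats.spec
    m = spec.n_items
    R = stats.correlation_matrix()
    l = _principal_factor_loadings(R, spec.reference_item)
    c = l / np.sqrt(np.clip(1.0 - l**2, 0.04, None))  # lambda_i * sqrt(phi) on unit-residual scale
    c_ref = c[spec.reference_item]
    if abs(c_ref) < 0.05:
        phi0 = 0.5
        lam0 = np.ones(m)
    else:
        phi0 = float(c_ref**2)
        lam0 = c / c_ref
    s = np.empty(m)
    for i, item in enumerate(spec.items):
        if item.is_ordinal:
            s[i] = np.sqrt(lam0[i] ** 2 * phi0 + 1.0)
        else:
            s[i] = np.sqrt(stats.numeric_vars[i])
    if pm.mu_free:
        a = pm.anchor_item
        mu0 = -stats.tau[a][0] * s[a] / lam0[a] if abs(lam0[a]) > 1e-6 else 0.0
    else:
        mu0 = 0.0
    x = np.zeros(pm.n_free)
    for i, (aa, bb, fixed_first) in pm.kappa_slices.items():
        kappa0 = stats.tau[i] * s[i] + lam0[i] * mu0
        if fixed_first:
            kappa0 = kappa0 - kappa0[0]  # honour the zero anchor
            x[aa:bb] = kappa0[1:]
        else:
            x[aa:bb] = kappa0
    x[pm.lam_slice[0] : pm.lam_slice[1]] = lam0[pm.lam_idx]
    for slot, i in enumerate(pm.num_idx):
        x[pm.pi_slice[0] + slot] = stats.numeric_means[i] - lam0[i] * mu0
        psi0 = max(stats.numeric_vars[i] - lam0[i] ** 2 * phi0, 0.05 * stats.numeric_vars[i])
        x[pm.logpsi_slice[0] + slot] = np.log(psi0)
    if pm.mu_free:
        x[pm.mu_pos] = mu0
    x[pm.logphi_pos] = np.log(phi0)
    return x


def fit_wls(stats: PolychoricStats, spec: ModelSpec | None = None) -> WLSFitResult:
    """Fit the model to the stacked statistics by DWLS; T uses the full weight matrix.

    ``spec`` defaults to the effective spec recorded in ``stats`` (which may
    have collapsed empty categories).
    """
    spec = stats.spec if spec is None else spec
    pm = _ParamMap(stats.spec)
    s_obs = stats.stat_vector
    dim = s_obs.size
    df = dim - pm.n_free
    if df <= 0:
        raise ValueError("model is not over-identified: df <= 0")
    w = np.sqrt(np.clip(np.diag(stats.gamma), 1e-10, None))

    def resid(x: np.ndarray) -> np.ndarray:
        return (s_obs - _implied_vector(pm.unpack(x), stats.spec)) / w

    x0 = _start_vector(stats, pm)
    sol = least_squares(resid, x0, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-10,
                        max_nfev=4000)
    params = pm.unpack(sol.x)
    mono = all(
        params.thresholds[i] is None or np.all(np.diff(params.thresholds[i]) > 0)
        or params.thresholds[i].size < 2
        for i in range(stats.spec.n_items)
    )
    converged = bool(sol.success) and mono and np.isfinite(sol.cost)

    r = s_obs - _implied_vector(params, stats.spec)
    T_d = float(stats.n * np.sum(r**2 / w**2))
    # scaled-shifted adjustment from the residual-weight operator U
    delta = -sol.jac * w[:, None]  # d sigma / d theta
    w_inv = 1.0 / w**2
    wd = delta * w_inv[:, None]
    try:
        proj = np.linalg.solve(delta.T @ wd, wd.T)
        UG = w_inv[:, None] * stats.gamma - wd @ (proj @ stats.gamma)
        tr1 = float(np.trace(UG))
        tr2 = float(np.trace(UG @ UG))
        a = np.sqrt(df / max(tr2, 1e-12))
        b = df - a * tr1
        T = max(a * T_d + b, 0.0)
    except np.linalg.LinAlgError:
        logger.warning("singular Jacobian in test-statistic adjustment; using raw DWLS T")
        T = max(T_d, 0.0)
    return WLSFitResult(
        spec=stats.spec,
        params=params,
        T=T,
        df=df,
        rmsea=rmsea(T, df, stats.n),
        converged=converged,
        n=stats.n,
        collapsed=stats.collapsed,
        dwls_objective=float(2.0 * sol.cost),
    )


def fit_wls_from_responses(responses: np.ndarray, spec: ModelSpec) -> WLSFitResult:
    """Convenience: polychoric stage plus DWLS fit in one call."""
    return fit_wls(estimate_polychoric(responses, spec))


def score_with_wls(fit: WLSFitResult, responses: np.ndarray, spec: ModelSpec) -> LatentScores:
    """EBM scores under a WLS fit, recoding responses if categories were collapsed."""
    y = np.asarray(responses, dtype=float).copy()
    for i, observed in fit.collapsed.items():
        K = spec.items[i].n_categories
        lut = np.zeros(K + 1, dtype=float)
        # map each original category to the nearest observed one (at or below, else first)
        eff = 0
        for orig in range(K):
            if eff + 1 < observed.size and orig >= observed[eff + 1]:
                eff += 1
            lut[orig + 1] = eff + 1
        y[:, i] = lut[y[:, i].astype(int)]
    return ebm_scores(fit.spec, fit.params, y)
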