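"""Limited-information sample statistics for ordinal/numeric item sets.

First stage of the WLS pipeline: univariate thresholds from cumulative
proportions, pairwise polychoric (ordinal-ordinal), polyserial
(numeric-ordinal) and Pearson (numeric-numeric) correlations estimated by
two-step maximum likelihood with thresholds held fixed, and an estimate of the
asymptotic covariance of the stacked statistics built from casewise influence
functions (with the threshold-estimation effect propagated into the
correlation influences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize_scalar
from scipy.special import ndtr
from scipy.stats import norm

from .model import ModelSpec, ItemSpec

__all__ = ["PolychoricStats", "estimate_polychoric", "bvn_cdf", "polychoric_from_table"]

logger = logging.getLogger(__name__)

_RHO_MAX = 0.999
_GL_NODES = 64
_gl_x, _gl_w = leggauss(_GL_NODES)


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X <= h, Y <= k) with correlation rho.

    Vectorized over h, k (broadcast); Gauss-Legendre quadrature of the
    correlation-derivative identity dPhi2/drho = phi2, accurate to ~1e-10 for
    |rho| <= 0.999.
    """
    h = np.clip(np.asarray(h, dtype=float), -12.0, 12.0)
    k = np.clip(np.asarray(k, dtype=float), -12.0, 12.0)
    base = ndtr(h) * ndtr(k)
    if rho == 0.0:
        return base
    # nodes on [0, rho]
    r = 0.5 * rho * (_gl_x + 1.0)
    w = 0.5 * abs(rho) * _gl_w
    hh = h[..., None]
    kk = k[..., None]
    om = 1.0 - r**2
    dens = np.exp(-(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )
    return base + np.sign(rho) * np.sum(dens * w, axis=-1)


def _bvn_pdf_grid(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """phi2 evaluated on the outer grid of cut points; zero at infinite cuts."""
    A, B = np.meshgrid(a, b, indexing="ij")
    out = np.zeros_like(A)
    fin = np.isfinite(A) & np.isfinite(B)
    om = 1.0 - rho**2
    Af, Bf = A[fin], B[fin]
    out[fin] = np.exp(-(Af**2 - 2 * rho * Af * Bf + Bf**2) / (2 * om)) / (
        2 * np.pi * np.sqrt(om)
    )
    return out


def _cell_probs(cuts_r: np.ndarray, cuts_c: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of the R x C table implied by rho and the cut points.

    cuts include -inf/+inf sentinels: length R+1 and C+1.
    """
    A, B = np.meshgrid(cuts_r, cuts_c, indexing="ij")
    cdf = np.where(
        (A <= -np.inf) | (B <= -np.inf),
        0.0,
        bvn_cdf(np.where(np.isfinite(A), A, 12.0), np.where(np.isfinite(B), B, 12.0), rho),
    )
    p = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(p, 1e-12, 1.0)


def _dcell_probs_drho(cuts_r: np.ndarray, cuts_c: np.ndarray, rho: float) -> np.ndarray:
    g = _bvn_pdf_grid(cuts_r, cuts_c, rho)
    return g[1:, 1:] - g[:-1, 1:] - g[1:, :-1] + g[:-1, :-1]


def polychoric_from_table(
    table: np.ndarray, tau_r: np.ndarray, tau_c: np.ndarray
) -> float:
    """Two-step ML polychoric correlation: thresholds fixed, rho by Brent search."""
    table = np.asarray(table, dtype=float)
    cuts_r = np.concatenate([[-np.inf], tau_r, [np.inf]])
    cuts_c = np.concatenate([[-np.inf], tau_c, [np.inf]])

    def nll(rho: float) -> float:
        p = _cell_probs(cuts_r, cuts_c, rho)
        return -float(np.sum(table * np.log(p)))

    res = minimize_scalar(
        nll, bounds=(-_RHO_MAX, _RHO_MAX), method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(res.x)
    if abs(rho) >= _RHO_MAX - 1e-4:
        rho = float(np.sign(rho) * _RHO_MAX)
        logger.warning("polychoric correlation clipped at %+.3f (near-perfect association)", rho)
    return rho


def _polyserial(z: np.ndarray, codes: np.ndarray, tau: np.ndarray) -> float:
    """Two-step ML polyserial correlation of standardized numeric z with an ordinal item."""
    cuts = np.concatenate([[-np.inf], tau, [np.inf]])
    lo = cuts[codes - 1]
    hi = cuts[codes]

    def nll(rho: float) -> float:
        w = np.sqrt(1.0 - rho**2)
        p = ndtr((hi - rho * z) / w) - ndtr((lo - rho * z) / w)
        return -float(np.sum(np.log(np.clip(p, 1e-12, None))))

    res = minimize_scalar(
        nll, bounds=(-_RHO_MAX, _RHO_MAX), method="bounded", options={"xatol": 1e-7}
    )
    rho = float(res.x)
    if abs(rho) >= _RHO_MAX - 1e-4:
        rho = float(np.sign(rho) * _RHO_MAX)
        logger.warning("polyserial correlation clipped at %+.3f", rho)
    return rho


def _polyserial_case_scores(
    z: np.ndarray, codes: np.ndarray, tau: np.ndarray, rho: float
) -> np.ndarray:
    """d/drho of the casewise conditional log-likelihood, by central difference."""
    cuts = np.concatenate([[-np.inf], tau, [np.inf]])
    lo, hi = cuts[codes - 1], cuts[codes]

    def loglik_case(r: float) -> np.ndarray:
        w = np.sqrt(1.0 - r**2)
        p = ndtr((hi - r * z) / w) - ndtr((lo - r * z) / w)
        return np.log(np.clip(p, 1e-12, None))

    h = 1e-5
    return (loglik_case(rho + h) - loglik_case(rho - h)) / (2 * h)


@dataclass
class PolychoricStats:
    """Stacked limited-information statistics for one sample.

    ``stat_vector`` orders thresholds item by item, then numeric means and
    variances, then correlations over item pairs (i < j).  ``gamma`` is the
    estimated asymptotic covariance of sqrt(n) * (s - sigma), so
    Var(s) ~= gamma / n.
    """

    spec: ModelSpec
    n: int
    tau: list[Optional[np.ndarray]]
    cum_props: list[Optional[np.ndarray]]
    numeric_means: dict[int, float]
    numeric_vars: dict[int, float]
    correlations: dict[tuple[int, int], float]
    corr_kinds: dict[tuple[int, int], str]
    stat_labels: list[str]
    gamma: np.ndarray
    collapsed: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def stat_vector(self) -> np.ndarray:
        vals: list[float] = []
        for i, item in enumerate(self.spec.items):
            if item.is_ordinal:
                vals.extend(self.tau[i].tolist())
            else:
                vals.append(self.numeric_means[i])
                vals.append(self.numeric_vars[i])
        m = self.spec.n_items
        for i in range(m):
            for j in range(i + 1, m):
                vals.append(self.correlations[(i, j)])
        return np.asarray(vals)

    @property
    def dim(self) -> int:
        return len(self.stat_labels)

    def correlation_matrix(self) -> np.ndarray:
        m = self.spec.n_items
        R = np.eye(m)
        for (i, j), r in self.correlations.items():
            R[i, j] = R[j, i] = r
        return R


def _recode_observed(codes: np.ndarray, n_categories: int, name: str):
    """Map 1..K codes to consecutive observed codes, collapsing empty categories."""
    counts = np.bincount(codes, minlength=n_categories + 1)[1:]
    observed = np.nonzero(counts)[0]  # 0-based original categories present
    if observed.size < 2:
        raise ValueError(f"item {name!r} shows fewer than 2 observed categories")
    if observed.size < n_categories:
        logger.info(
            "item %r: %d empty categories collapsed with neighbours",
            name, n_categories - observed.size,
        )
    lut = np.zeros(n_categories + 1, dtype=int)
    lut[observed + 1] = np.arange(1, observed.size + 1)
    return lut[codes], observed.size, observed


def estimate_polychoric(responses: np.ndarray, spec: ModelSpec) -> PolychoricStats:
    """Thresholds, pairwise correlations and their joint asymptotic covariance."""
    y = np.asarray(responses, dtype=float)
    n, m = y.shape
    if m != spec.n_items:
        raise ValueError("response matrix does not match the model spec")

    eff_items: list[ItemSpec] = []
    codes = np.zeros((n, m), dtype=int)
    collapsed: dict[int, np.ndarray] = {}
    for i, item in enumerate(spec.items):
        if item.is_ordinal:
            c = y[:, i].astype(int)
            if np.any((c < 1) | (c > item.n_categories)) or np.any(c != y[:, i]):
                raise ValueError(f"item {item.name!r}: codes outside 1..{item.n_categories}")
            rec, k_eff, observed = _recode_observed(c, item.n_categories, item.name)
            codes[:, i] = rec
            if k_eff < item.n_categories:
                collapsed[i] = observed
            eff_items.append(ItemSpec(item.name, "ordinal", k_eff))
        else:
            eff_items.append(item)
    eff_spec = ModelSpec(items=tuple(eff_items), reference_item=spec.reference_item)

    tau: list[Optional[np.ndarray]] = [None] * m
    cum_props: list[Optional[np.ndarray]] = [None] * m
    z = np.zeros((n, m))  # standardized numeric columns
    numeric_means: dict[int, float] = {}
    numeric_vars: dict[int, float] = {}
    labels: list[str] = []
    omega_cols: list[np.ndarray] = []  # casewise influences, one column per statistic

    for i, item in enumerate(eff_spec.items):
        if item.is_ordinal:
            K = item.n_categories
            counts = np.bincount(codes[:, i], minlength=K + 1)[1:]
            cp = np.cumsum(counts)[:-1] / n  # cumulative proportions below cut k
            tau[i] = norm.ppf(cp)
            cum_props[i] = cp
            dens = norm.pdf(tau[i])
            for k in range(K - 1):
                ind = (codes[:, i] <= k + 1).astype(float)
                omega_cols.append((ind - cp[k]) / dens[k])
                labels.append(f"tau[{item.name},{k + 1}]")
        else:
            x = y[:, i]
            mu = float(x.mean())
            v = float(x.var())  # ML divisor n
            numeric_means[i] = mu
            numeric_vars[i] = v
            z[:, i] = (x - mu) / np.sqrt(v)
            omega_cols.append(x - mu)
            labels.append(f"mean[{item.name}]")
            omega_cols.append((x - mu) ** 2 - v)
            labels.append(f"var[{item.name}]")

    # column index of threshold tau[i][k] in the omega/label stack
    col_of_tau: dict[int, int] = {}
    pos = 0
    for i, item in enumerate(eff_spec.items):
        if item.is_ordinal:
            col_of_tau[i] = pos
            pos += item.n_categories - 1
        else:
            pos += 2

    correlations: dict[tuple[int, int], float] = {}
    corr_kinds: dict[tuple[int, int], str] = {}
    h = 1e-4
    for i in range(m):
        for j in range(i + 1, m):
            it_i, it_j = eff_spec.items[i], eff_spec.items[j]
            if it_i.is_ordinal and it_j.is_ordinal:
                Ki, Kj = it_i.n_categories, it_j.n_categories
                table = np.zeros((Ki, Kj))
                np.add.at(table, (codes[:, i] - 1, codes[:, j] - 1), 1.0)
                rho = polychoric_from_table(table, tau[i], tau[j])
                phat = table / n

                def mean_score(r, ti, tj):
                    cr = np.concatenate([[-np.inf], ti, [np.inf]])
                    cc = np.concatenate([[-np.inf], tj, [np.inf]])
                    s = _dcell_probs_drho(cr, cc, r) / _cell_probs(cr, cc, r)
                    return float(np.sum(phat * s)), s

                _, s_cells = mean_score(rho, tau[i], tau[j])
                J_rho = (
                    mean_score(rho + h, tau[i], tau[j])[0]
                    - mean_score(rho - h, tau[i], tau[j])[0]
                ) / (2 * h)
                g_case = s_cells[codes[:, i] - 1, codes[:, j] - 1]
                corr_term = np.zeros(n)
                for side, idx in ((i, tau[i]), (j, tau[j])):
                    for t in range(idx.size):
                        tp, tmn = idx.copy(), idx.copy()
                        tp[t] += h
                        tmn[t] -= h
                        if side == i:
                            gp = mean_score(rho, tp, tau[j])[0]
                            gm = mean_score(rho, tmn, tau[j])[0]
                        else:
                            gp = mean_score(rho, tau[i], tp)[0]
                            gm = mean_score(rho, tau[i], tmn)[0]
                        J_t = (gp - gm) / (2 * h)
                        corr_term += J_t * omega_cols[col_of_tau[side] + t]
                omega_rho = -(g_case + corr_term) / J_rho
                correlations[(i, j)] = rho
                corr_kinds[(i, j)] = "polychoric"
                omega_cols.append(omega_rho)
            elif not it_i.is_ordinal and not it_j.is_ordinal:
                r = float(np.corrcoef(y[:, i], y[:, j])[0, 1])
                correlations[(i, j)] = r
                corr_kinds[(i, j)] = "pearson"
                omega_cols.append(
                    z[:, i] * z[:, j] - 0.5 * r * (z[:, i] ** 2 + z[:, j] ** 2)
                )
            else:
                num, ord_ = (i, j) if not it_i.is_ordinal else (j, i)
                rho = _polyserial(z[:, num], codes[:, ord_], tau[ord_])
                g_case = _polyserial_case_scores(z[:, num], codes[:, ord_], tau[ord_], rho)
                J_rho = (
                    np.mean(
                        _polyserial_case_scores(
                            z[:, num], codes[:, ord_], tau[ord_], rho + h
                        )
                    )
                    - np.mean(
                        _polyserial_case_scores(
                            z[:, num], codes[:, ord_], tau[ord_], rho - h
                        )
                    )
                ) / (2 * h)
                corr_term = np.zeros(n)
                tt = tau[ord_]
                for t in range(tt.size):
                    tp, tmn = tt.copy(), tt.copy()
                    tp[t] += h
                    tmn[t] -= h
                    J_t = (
                        np.mean(_polyserial_case_scores(z[:, num], codes[:, ord_], tp, rho))
                        - np.mean(_polyserial_case_scores(z[:, num], codes[:, ord_], tmn, rho))
                    ) / (2 * h)
                    corr_term += J_t * omega_cols[col_of_tau[ord_] + t]
                correlations[(i, j)] = rho
                corr_kinds[(i, j)] = "polyserial"
                omega_cols.append(-(g_case - np.mean(g_case) + corr_term) / J_rho)
            labels.append(f"rho[{eff_spec.items[i].name},{eff_spec.items[j].name}]")

    omega = np.column_stack(omega_cols)
    omega = omega - omega.mean(axis=0)
    gamma = omega.T @ omega / n

    return PolychoricStats(
        spec=eff_spec,
        n=n,
        tau=tau,
        cum_props=cum_props,
        numeric_means=numeric_means,
        numeric_vars=numeric_vars,
        correlations=correlations,
        corr_kinds=corr_kinds,
        stat_labels=labels,
        gamma=gamma,
        collapsed=collapsed,
    )
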