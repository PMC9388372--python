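"""Multivariate random-effects meta-regression of city exposure-response curves.

Each city i contributes a 4-vector of lag-cumulated spline coefficients y_i
with known within-city covariance S_i.  The model is

    y_i ~ N( (u_i' B)' , S_i + Psi )

with u_i the meta-predictors (intercept, median observed temperature,
temperature range, country indicators), B the p x 4 fixed-effect matrix and
Psi the 4 x 4 between-city covariance.  Estimation is restricted maximum
likelihood with Psi parameterised through its Cholesky factor (log-diagonal),
which keeps it positive semidefinite; the fixed effects are profiled out by
GLS at each Psi.

BLUP ("smoothed") city curves shrink each city's own estimate toward its
meta-regression prediction in proportion to its within-city imprecision:

    blup_i = m_i + Psi (Psi + S_i)^{-1} (y_i - m_i),     m_i = B' u_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .splines import ReducedCurve

__all__ = [
    "MetaModel",
    "SmoothedCityCurve",
    "build_meta_predictors",
    "fit_meta_regression",
    "blup",
    "pooled_curve",
]


@dataclass
class MetaModel:
    """Fitted multivariate random-effects meta-regression."""

    fixed_effects: np.ndarray  # p x k
    vcov_fixed: np.ndarray  # (p*k) x (p*k), vec ordering row-major in (u, outcome)
    psi: np.ndarray  # k x k between-city covariance
    predictor_names: list[str]
    country_levels: list[str]
    restricted_loglik: float
    converged: bool
    n_cities: int

    @property
    def k(self) -> int:
        return self.fixed_effects.shape[1]

    def design_row(self, median_temp: float, temp_range: float, country: str) -> np.ndarray:
        u = [1.0, float(median_temp), float(temp_range)]
        for lvl in self.country_levels[1:]:
            u.append(1.0 if country == lvl else 0.0)
        if country not in self.country_levels:
            raise ValueError(f"unknown country {country!r}; model levels: {self.country_levels}")
        return np.asarray(u)

    def predict_coef(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fixed-effects prediction B'u and its delta-method covariance."""
        u = np.asarray(u, dtype=float)
        mean = self.fixed_effects.T @ u
        A = np.kron(u[None, :], np.eye(self.k))  # k x (p*k)
        return mean, A @ self.vcov_fixed @ A.T


@dataclass
class SmoothedCityCurve:
    """A city's BLUP curve: shrunk coefficients with conditional covariance."""

    city_id: str
    curve: ReducedCurve
    shrinkage: np.ndarray  # K = Psi (Psi + S_i)^{-1}


def build_meta_predictors(
    series_list,
    country_merge: dict[str, str] | None = None,
    range_definition: str = "minmax",
) -> pd.DataFrame:
    """Meta-predictor table: median temperature, temperature range, country.

    ``range_definition`` is ``"minmax"`` (max - min of daily means, the
    default) or ``"iqr"``.  ``country_merge`` maps raw country labels onto
    merged groups (e.g. several small countries pooled into one).
    """
    rows = []
    for s in series_list:
        t = np.asarray(s.temp_c, dtype=float)
        if range_definition == "minmax":
            rng = float(t.max() - t.min())
        elif range_definition == "iqr":
            rng = float(np.percentile(t, 75) - np.percentile(t, 25))
        else:
            raise ValueError(f"unknown range definition {range_definition!r}")
        country = s.country
        if country_merge:
            country = country_merge.get(country, country)
        rows.append({
            "city_id": s.city_id,
            "median_temp": float(np.median(t)),
            "temp_range": rng,
            "country": country,
        })
    return pd.DataFrame(rows)


def _design_matrix(predictors: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    levels = sorted(predictors["country"].unique())
    cols = [np.ones(len(predictors)), predictors["median_temp"].to_numpy(dtype=float),
            predictors["temp_range"].to_numpy(dtype=float)]
    names = ["intercept", "median_temp", "temp_range"]
    for lvl in levels[1:]:
        cols.append((predictors["country"] == lvl).to_numpy(dtype=float))
        names.append(f"country[{lvl}]")
    return np.column_stack(cols), names, levels


def _chol_from_params(params: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.diag_indices(k)] = np.exp(params[:k])
    L[np.tril_indices(k, -1)] = params[k:]
    return L


def _params_from_psi(psi: np.ndarray, k: int) -> np.ndarray:
    jitter = 1e-8 * np.trace(psi) / k + 1e-12
    L = np.linalg.cholesky(psi + jitter * np.eye(k))
    return np.concatenate([np.log(np.diag(L)), L[np.tril_indices(k, -1)]])


def _reml_pieces(Y, S, U, psi):
    """GLS fixed effects and restricted log-likelihood at a given Psi.

    The city design is X_i = kron(u_i, I_k), so the GLS cross-products have
    Kronecker structure and everything vectorises over cities with numpy's
    batched linear algebra.
    """
    n, k = Y.shape
    p = U.shape[1]
    V = S + psi[None, :, :]  # n x k x k
    sign, logdet = np.linalg.slogdet(V)
    if (sign <= 0).any():
        return None
    W = np.linalg.inv(V)
    # XtVX[(a,i),(b,j)] = sum_c U[c,a] U[c,b] W[c,i,j]
    XtVX = np.einsum("ca,cb,cij->aibj", U, U, W).reshape(p * k, p * k)
    XtVy = np.einsum("ca,cij,cj->ai", U, W, Y).reshape(p * k)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return None
    R = Y - U @ beta.reshape(p, k)  # residuals, n x k
    quad = float(np.einsum("ci,cij,cj->", R, W, R))
    sign_x, logdet_x = np.linalg.slogdet(XtVX)
    if sign_x <= 0:
        return None
    reml = -0.5 * (float(logdet.sum()) + logdet_x + quad)
    return beta, XtVX, reml


def fit_meta_regression(
    curves: list[ReducedCurve],
    predictors: pd.DataFrame,
    intercept_only: bool = False,
    fix_psi: np.ndarray | None = None,
) -> MetaModel:
    """REML fit of the multivariate random-effects meta-regression.

    Parameters
    ----------
    curves
        Per-city reduced curves (coef + vcov), one per predictor row, aligned
        by position.
    predictors
        Output of :func:`build_meta_predictors` (columns ``city_id``,
        ``median_temp``, ``temp_range``, ``country``).
    intercept_only
        Drop all meta-predictors, pooling with a common mean (classical
        multivariate random-effects meta-analysis).
    fix_psi
        Skip REML and hold the between-city covariance at this matrix
        (e.g. zeros for a fixed-effect pooling).
    """
    n = len(curves)
    if n != len(predictors):
        raise ValueError("one predictor row per curve required")
    k = curves[0].coef.size
    Y = np.stack([c.coef for c in curves])
    S = np.stack([c.vcov for c in curves])
    for i, c in enumerate(curves):
        if not np.all(np.isfinite(np.linalg.cholesky(c.vcov + 1e-12 * np.eye(k)))):
            raise ValueError(f"singular within-city vcov for city {c.city_id}")
    if intercept_only:
        U = np.ones((n, 1))
        names, levels = ["intercept"], sorted(predictors["country"].unique())
    else:
        U, names, levels = _design_matrix(predictors)
    p = U.shape[1]
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} cities for {p} predictor terms")

    if fix_psi is not None:
        psi = np.asarray(fix_psi, dtype=float)
        converged = True
    else:
        # moment start: between-city covariance of residual coefficient spread
        psi0 = np.cov(Y.T) - S.mean(axis=0) if n > 1 else np.eye(k)
        w, V = np.linalg.eigh(0.5 * (psi0 + psi0.T))
        psi0 = (V * np.maximum(w, 1e-4)) @ V.T
        x0 = _params_from_psi(psi0, k)

        def nll(params):
            L = _chol_from_params(params, k)
            pieces = _reml_pieces(Y, S, U, L @ L.T)
            if pieces is None:
                return 1e12
            return -pieces[2]

        res = optimize.minimize(nll, x0, method="BFGS",
                                options={"maxiter": 300, "gtol": 1e-7})
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-9})
        best = res2 if res2.fun <= res.fun else res
        L = _chol_from_params(best.x, k)
        psi = L @ L.T
        converged = bool(res.success or res2.success)
    beta, XtVX, reml = _reml_pieces(Y, S, U, psi)
    vcov_fixed = np.linalg.inv(XtVX)
    B = beta.reshape(p, k)  # X_i = kron(u_i, I_k) => beta blocks are rows of B
    return MetaModel(
        fixed_effects=B,
        vcov_fixed=0.5 * (vcov_fixed + vcov_fixed.T),
        psi=0.5 * (psi + psi.T),
        predictor_names=names,
        country_levels=levels,
        restricted_loglik=float(reml),
        converged=converged,
        n_cities=n,
    )


def blup(model: MetaModel, curve: ReducedCurve, u: np.ndarray) -> SmoothedCityCurve:
    """Best linear unbiased prediction of one city's curve coefficients.

    The conditional covariance combines the posterior spread
    Psi - K Psi (K the shrinkage matrix) with the propagated fixed-effect
    uncertainty (I - K) X V_beta X' (I - K)'.
    """
    u = np.asarray(u, dtype=float)
    if u.size != model.fixed_effects.shape[0]:
        raise ValueError("predictor vector length does not match the fitted model")
    k = model.k
    mean, mean_cov = model.predict_coef(u)
    S = curve.vcov
    K = model.psi @ np.linalg.inv(model.psi + S)
    coef = mean + K @ (curve.coef - mean)
    I_K = np.eye(k) - K
    cond = model.psi - K @ model.psi + I_K @ mean_cov @ I_K.T
    cond = 0.5 * (cond + cond.T)
    new_curve = ReducedCurve(coef, cond, curve.exposure_spec, curve.ref_temp, curve.city_id)
    return SmoothedCityCurve(city_id=curve.city_id or "", curve=new_curve, shrinkage=K)


def pooled_curve(
    model: MetaModel,
    u: np.ndarray,
    exposure_spec,
    ref_temp: float,
) -> ReducedCurve:
    """Fixed-effects ("overall") curve at the supplied meta-predictor values."""
    mean, cov = model.predict_coef(np.asarray(u, dtype=float))
    return ReducedCurve(mean, 0.5 * (cov + cov.T), exposure_spec, float(ref_temp), "pooled")
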