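"""City-specific conditional Poisson distributed-lag fits.

Each city's daily counts are modelled as Poisson with a log link, the
cross-basis columns as regressors, log annual population as offset, and a
separate intercept for every day-of-week x month x year stratum.  Rather than
estimating the thousands of stratum intercepts, the likelihood is conditioned
on the stratum death totals, which eliminates them exactly: given the total
Y_s of stratum s, the counts are multinomial with day probabilities

    p_i = exp(eta_i) / sum_{j in s} exp(eta_j),    eta_i = x_i' beta + offset_i.

The conditional maximum-likelihood estimate coincides with the fixed-effects
Poisson estimate (a standard equivalence), which the test suite checks
against an explicit-dummy GLM fit.  Estimation is by Newton's method with
step halving on the exact conditional log-likelihood, gradient and Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import CrossBasis

__all__ = [
    "FirstStageFit",
    "make_strata",
    "fit_conditional_poisson",
    "fit_from_arrays",
    "empirical_percentile",
]

MAX_LAG = 21


@dataclass
class FirstStageFit:
    """Cross-basis coefficients and covariance from one conditional Poisson fit."""

    city_id: str
    coef: np.ndarray
    vcov: np.ndarray
    n_strata_used: int
    n_strata_dropped: int
    n_days_used: int
    converged: bool
    dispersion: float
    loglik: float

    def wald_statistic(self) -> float:
        """Wald chi-square for the full cross-basis coefficient block."""
        return float(self.coef @ np.linalg.solve(self.vcov, self.coef))


def make_strata(dates: pd.DatetimeIndex, city_ids: np.ndarray | None = None) -> np.ndarray:
    """Stratum label per day: (year, month, day-of-week), optionally x city.

    Days share a stratum iff they share all components, so strata never span
    calendar years and seasonality/secular trends are controlled by design.
    Returns an object array of tuples.
    """
    dates = pd.DatetimeIndex(dates)
    parts = [np.asarray(dates.year), np.asarray(dates.month), np.asarray(dates.dayofweek)]
    if city_ids is not None:
        parts = [np.asarray(city_ids)] + parts
    out = np.empty(len(dates), dtype=object)
    out[:] = list(zip(*parts))
    return out


def empirical_percentile(temps: np.ndarray, p: float) -> float:
    """Linear-interpolation empirical quantile of a temperature series."""
    x = np.asarray(temps, dtype=float)
    if x.size == 0:
        raise ValueError("empty temperature series")
    if not 0.0 <= p <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(x, p))


def _conditional_loglik_parts(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray, seg_starts: np.ndarray,
    totals: np.ndarray, beta: np.ndarray,
):
    """Log-likelihood, gradient, Hessian of the stratum-conditioned model.

    Arrays must already be sorted by stratum; ``seg_starts`` indexes the first
    row of each stratum and ``totals`` holds stratum death totals.
    """
    eta = X @ beta + offset
    seg_max = np.maximum.reduceat(eta, seg_starts)
    n_per = np.diff(np.append(seg_starts, len(eta)))
    e = np.exp(eta - np.repeat(seg_max, n_per))
    seg_sum = np.add.reduceat(e, seg_starts)
    p = e / np.repeat(seg_sum, n_per)
    mu = np.repeat(totals, n_per) * p  # conditional fitted means
    ll = float(y @ eta - totals @ (np.log(seg_sum) + seg_max))
    grad = X.T @ (y - mu)
    # H = X' diag(mu) X - sum_s (X' mu_s)(X' mu_s)' / Y_s
    XtmuX = (X * mu[:, None]).T @ X
    T = np.add.reduceat(X * mu[:, None], seg_starts, axis=0)  # strata x p
    H = XtmuX - (T / totals[:, None]).T @ T
    return ll, grad, H, mu


def fit_from_arrays(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    strata: np.ndarray,
    city_id: str = "",
    tol: float = 1e-9,
    max_iter: int = 100,
    scale_vcov_by_dispersion: bool = False,
) -> FirstStageFit:
    """Maximise the stratum-conditioned Poisson likelihood on raw arrays.

    Strata whose death total is zero are dropped (they carry no conditional
    information); their count is reported on the fit.  Raises on
    non-convergence rather than returning a silently bad fit.
    """
    y = np.asarray(y, dtype=float)
    if y.sum() == 0:
        raise ValueError(f"outcome has no deaths ({city_id or 'unnamed series'})")
    codes, _ = pd.factorize(strata, sort=True)
    order = np.argsort(codes, kind="stable")
    X, y, offset, codes = X[order], y[order], offset[order], codes[order]
    seg_starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    totals = np.add.reduceat(y, seg_starts)

    keep_strata = totals > 0
    n_dropped = int((~keep_strata).sum())
    n_per = np.diff(np.append(seg_starts, len(y)))
    keep_rows = np.repeat(keep_strata, n_per)
    X, y, offset, codes = X[keep_rows], y[keep_rows], offset[keep_rows], codes[keep_rows]
    seg_starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    totals = totals[keep_strata]
    if totals.size == 0:
        raise ValueError("no informative strata")

    p = X.shape[1]
    # centring columns leaves within-stratum contrasts (and the fit) unchanged
    X = X - X.mean(axis=0)
    beta = np.zeros(p)
    ll, grad, H, mu = _conditional_loglik_parts(X, y, offset, seg_starts, totals, beta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(30):  # step halving on the exact conditional log-likelihood
            cand = beta + scale * step
            new = _conditional_loglik_parts(X, y, offset, seg_starts, totals, cand)
            if new[0] >= ll - 1e-12:
                break
            scale *= 0.5
        rel = abs(new[0] - ll) / (abs(ll) + 1e-10)
        beta, (ll, grad, H, mu) = cand, new
        if rel < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"conditional Poisson fit did not converge ({city_id})")

    vcov = np.linalg.inv(H)
    vcov = 0.5 * (vcov + vcov.T)
    resid_df = max(len(y) - len(totals) - p, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.where(mu > 0, (y - mu) ** 2 / mu, 0.0).sum()
    dispersion = float(pearson / resid_df)
    if scale_vcov_by_dispersion:
        vcov = vcov * max(1.0, dispersion)
    return FirstStageFit(
        city_id=city_id,
        coef=beta,
        vcov=vcov,
        n_strata_used=len(totals),
        n_strata_dropped=n_dropped,
        n_days_used=len(y),
        converged=converged,
        dispersion=dispersion,
        loglik=ll,
    )


def fit_conditional_poisson(
    series,
    crossbasis: CrossBasis,
    outcome: str = "deaths_all",
    drop_burn_in: bool = True,
    tol: float = 1e-9,
    max_iter: int = 100,
    scale_vcov_by_dispersion: bool = False,
) -> FirstStageFit:
    """Fit the stratum-conditioned Poisson distributed-lag model for one city.

    Parameters
    ----------
    series
        A :class:`~tempmort.synthetic.DailyCitySeries` (or any object with the
        same ``dates``/``deaths``/``population_offset`` surface).
    crossbasis
        Cross-basis built from the city's temperature series.
    outcome
        Death-count column to model (e.g. ``deaths_all``, ``deaths_65plus``).
    drop_burn_in
        Drop the first ``max_lag`` days, whose exposure history is padded.
    scale_vcov_by_dispersion
        If true, multiply vcov by max(1, Pearson dispersion).
    """
    if outcome not in series.deaths.columns:
        raise ValueError(f"unknown outcome column {outcome!r}")
    if np.ptp(crossbasis.exposure_series) == 0:
        raise ValueError("temperature series has no variation")
    start = crossbasis.spec.max_lag if drop_burn_in else 0
    return fit_from_arrays(
        crossbasis.matrix[start:],
        series.deaths[outcome].to_numpy(dtype=float)[start:],
        series.population_offset()[start:],
        make_strata(series.dates)[start:],
        city_id=series.city_id,
        tol=tol,
        max_iter=max_iter,
        scale_vcov_by_dispersion=scale_vcov_by_dispersion,
    )
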