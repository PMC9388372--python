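"""Natural cubic spline bases, the temperature x lag cross-basis, and curve algebra.

The exposure-response surface is parameterised by a tensor ("cross") basis: a
natural cubic spline in temperature crossed with a natural cubic spline in lag
(0-21 days).  Summing the fitted surface over integer lags collapses it to a
low-dimensional lag-cumulated curve, the object that is pooled across cities
and used for all risk summaries.

Natural cubic splines are cubic between knots, have continuous second
derivatives, and are constrained to be linear at and beyond the boundary
knots.  The basis here is the classical truncated-power construction: with
knots ``k_1 < ... < k_K`` (boundary knots first and last) define

    d_j(x) = [ (x - k_j)_+^3 - (x - k_K)_+^3 ] / (k_K - k_j)

and take ``{1, x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}}``.  Each function is
linear outside the boundary knots, so extrapolation is linear by
construction.  Without the intercept the dimension is ``K - 1`` =
(number of internal knots) + 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasis",
    "ReducedCurve",
    "natural_cubic_basis",
    "build_cross_basis",
    "reduce_to_overall",
    "predict_curve",
    "default_lag_spec",
]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a natural cubic spline basis.

    Parameters
    ----------
    boundary_knots
        (low, high) pair; the basis is linear at and beyond these.
    internal_knots
        Strictly increasing knots strictly inside the boundaries.
    include_intercept
        Whether the constant function is part of the basis.
    """

    boundary_knots: tuple[float, float]
    internal_knots: tuple[float, ...]
    include_intercept: bool = False

    def __post_init__(self) -> None:
        lo, hi = map(float, self.boundary_knots)
        if not np.isfinite([lo, hi]).all() or lo >= hi:
            raise ValueError(f"invalid boundary knots ({lo}, {hi})")
        ik = tuple(float(k) for k in self.internal_knots)
        if any(not np.isfinite(k) for k in ik):
            raise ValueError("non-finite internal knot")
        if any(k <= lo or k >= hi for k in ik):
            raise ValueError("internal knots must lie strictly inside the boundary knots")
        if any(b <= a for a, b in zip(ik, ik[1:])):
            raise ValueError("internal knots must be strictly increasing")
        object.__setattr__(self, "boundary_knots", (lo, hi))
        object.__setattr__(self, "internal_knots", ik)

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.asarray([lo, *self.internal_knots, hi], dtype=float)

    @property
    def df(self) -> int:
        return len(self.internal_knots) + 1 + int(self.include_intercept)

    @classmethod
    def from_percentiles(
        cls,
        values: np.ndarray,
        percentiles: tuple[float, ...] = (10.0, 75.0, 90.0),
        include_intercept: bool = False,
    ) -> "SplineSpec":
        """Knots at the min, max and the given percentiles of ``values``.

        This is the layout used for the temperature dimension: boundary knots
        at the observed minimum and maximum, internal knots at the 10th, 75th
        and 90th percentiles by default.
        """
        x = np.asarray(values, dtype=float)
        if x.size == 0 or not np.isfinite(x).all():
            raise ValueError("values must be nonempty and finite")
        internal = tuple(np.percentile(x, list(percentiles)))
        return cls((float(x.min()), float(x.max())), internal, include_intercept)

    def to_dict(self) -> dict:
        return {
            "boundary_knots": list(self.boundary_knots),
            "internal_knots": list(self.internal_knots),
            "include_intercept": self.include_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            tuple(d["boundary_knots"]),
            tuple(d["internal_knots"]),
            bool(d["include_intercept"]),
        )


def natural_cubic_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x`` (n x df matrix).

    Values outside the boundary knots are allowed; every basis function is
    linear there (zero second derivative at and beyond the boundaries).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("x must be finite")
    knots = spec.all_knots
    K = knots.size
    k_last = knots[-1]
    denom_last = None  # d_{K-1} shared by every column

    def d(j: int) -> np.ndarray:
        return (
            np.maximum(x - knots[j], 0.0) ** 3 - np.maximum(x - k_last, 0.0) ** 3
        ) / (k_last - knots[j])

    d_pen = d(K - 2)
    cols = [x] + [d(j) - d_pen for j in range(K - 2)]
    if spec.include_intercept:
        cols = [np.ones_like(x)] + cols
    return np.column_stack(cols)


def default_lag_spec(max_lag: int = 21, n_internal: int = 3) -> SplineSpec:
    """Natural cubic spline over the lag axis, with intercept.

    Internal knots are equally spaced on the log(lag + 1) scale, the
    conventional layout for distributed-lag models where early lags carry
    most of the structure.
    """
    u = np.linspace(0.0, np.log(max_lag + 1.0), n_internal + 2)
    internal = tuple(np.exp(u[1:-1]) - 1.0)
    return SplineSpec((0.0, float(max_lag)), internal, include_intercept=True)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Specification of the temperature x lag tensor basis."""

    exposure_spec: SplineSpec
    lag_spec: SplineSpec = field(default_factory=default_lag_spec)
    max_lag: int = 21

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")

    @property
    def n_columns(self) -> int:
        return self.exposure_spec.df * self.lag_spec.df

    def to_dict(self) -> dict:
        return {
            "exposure_spec": self.exposure_spec.to_dict(),
            "lag_spec": self.lag_spec.to_dict(),
            "max_lag": self.max_lag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            SplineSpec.from_dict(d["exposure_spec"]),
            SplineSpec.from_dict(d["lag_spec"]),
            int(d["max_lag"]),
        )


@dataclass
class CrossBasis:
    """Days x (exposure df * lag df) design matrix for the lagged surface.

    Row ``t`` depends only on exposures at days ``t, t-1, ..., t-max_lag``;
    pre-series history is back-filled with the first observed value, and
    callers fitting models drop the first ``max_lag`` rows.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    exposure_series: np.ndarray


def _lagged_matrix(x: np.ndarray, max_lag: int) -> np.ndarray:
    """n x (max_lag+1) matrix whose column l holds x shifted down by l days."""
    n = x.size
    padded = np.concatenate([np.full(max_lag, x[0]), x])
    idx = np.arange(n)[:, None] + max_lag - np.arange(max_lag + 1)[None, :]
    return padded[idx]


def build_cross_basis(temps: np.ndarray, spec: CrossBasisSpec) -> CrossBasis:
    """Construct the tensor cross-basis from a daily temperature series.

    Entry (t, j * lag_df + k) = sum over lags l of
    ``exposure_basis_j(x_{t-l}) * lag_basis_k(l)``.
    """
    x = np.asarray(temps, dtype=float)
    if x.ndim != 1 or x.size <= spec.max_lag:
        raise ValueError(f"series must be 1-D and longer than max_lag={spec.max_lag}")
    Q = _lagged_matrix(x, spec.max_lag)  # n x (L+1)
    n, L1 = Q.shape
    R = natural_cubic_basis(Q.ravel(), spec.exposure_spec).reshape(n, L1, -1)
    C = natural_cubic_basis(np.arange(L1, dtype=float), spec.lag_spec)  # (L+1) x vl
    cb = np.einsum("nlj,lk->njk", R, C).reshape(n, -1)
    return CrossBasis(matrix=cb, spec=spec, exposure_series=x)


@dataclass
class ReducedCurve:
    """Lag-cumulated exposure-response curve: coefficients, covariance, centering.

    The predicted log relative risk at temperature ``x`` is
    ``(b(x) - b(ref_temp)) @ coef`` with ``b`` the exposure spline basis, so
    the curve is exactly zero at ``ref_temp`` and re-centering is exact.
    """

    coef: np.ndarray
    vcov: np.ndarray
    exposure_spec: SplineSpec
    ref_temp: float
    city_id: str | None = None

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        k = self.exposure_spec.df
        if self.coef.shape != (k,) or self.vcov.shape != (k, k):
            raise ValueError("coef/vcov dimensions do not match the exposure basis")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
            raise ValueError("vcov must be symmetric")
        self.vcov = 0.5 * (self.vcov + self.vcov.T)

    def centred_basis(self, temps: np.ndarray) -> np.ndarray:
        b = natural_cubic_basis(np.atleast_1d(temps), self.exposure_spec)
        b_ref = natural_cubic_basis(np.array([self.ref_temp]), self.exposure_spec)
        return b - b_ref

    def predict(self, temps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Log-RR (relative to ref_temp) and delta-method pointwise SE."""
        Bd = self.centred_basis(temps)
        log_rr = Bd @ self.coef
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Bd, self.vcov, Bd), 0.0))
        return log_rr, se

    def recenter(self, new_ref: float) -> "ReducedCurve":
        return ReducedCurve(
            self.coef.copy(), self.vcov.copy(), self.exposure_spec, float(new_ref), self.city_id
        )


def reduce_to_overall(
    coef: np.ndarray,
    vcov: np.ndarray,
    spec: CrossBasisSpec,
    ref_temp: float,
    city_id: str | None = None,
) -> ReducedCurve:
    """Sum the fitted surface over integer lags 0..max_lag.

    The reduction matrix M has one row per exposure basis column; pooling the
    lag basis at integer lags gives reduced coef = M @ coef and reduced
    vcov = M @ vcov @ M'.
    """
    coef = np.asarray(coef, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    vx, vl = spec.exposure_spec.df, spec.lag_spec.df
    if coef.shape != (vx * vl,) or vcov.shape != (vx * vl, vx * vl):
        raise ValueError("coefficient dimensions do not match the cross-basis spec")
    lags = np.arange(spec.max_lag + 1, dtype=float)
    s = natural_cubic_basis(lags, spec.lag_spec).sum(axis=0)  # length vl
    M = np.kron(np.eye(vx), s[None, :])  # vx x (vx*vl)
    return ReducedCurve(M @ coef, M @ vcov @ M.T, spec.exposure_spec, float(ref_temp), city_id)


def predict_curve(
    curve: ReducedCurve, temps: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log-RR and pointwise SE of a reduced curve on a temperature grid."""
    return curve.predict(temps)


def curve_to_dict(curve: ReducedCurve) -> dict:
    return {
        "city_id": curve.city_id,
        "coef": curve.coef.tolist(),
        "vcov": curve.vcov.tolist(),
        "exposure_spec": curve.exposure_spec.to_dict(),
        "ref_temp": curve.ref_temp,
    }


def curve_from_dict(d: dict) -> ReducedCurve:
    return ReducedCurve(
        np.asarray(d["coef"]),
        np.asarray(d["vcov"]),
        SplineSpec.from_dict(d["exposure_spec"]),
        float(d["ref_temp"]),
        d.get("city_id"),
    )


def spec_to_json(spec: CrossBasisSpec) -> str:
    return json.dumps(spec.to_dict(), indent=2)
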