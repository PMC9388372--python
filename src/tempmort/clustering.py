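"""Grouping cities by their daily-temperature distributions.

Cause-specific daily counts are often too sparse for city-level fits, so
cities are grouped by the shape of their full temperature distribution: each
city's empirical CDF evaluated on a common temperature grid is the feature
vector, and cities are merged by Ward's minimum-variance agglomerative
clustering on Euclidean feature distance.  One conditional Poisson model is
then fitted per cluster on the concatenated series, with city identifier
added to the conditioning strata (city x year x month x day-of-week) and
exposure-spline knots taken from the pooled within-cluster temperature
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .first_stage import FirstStageFit, fit_from_arrays, make_strata
from .splines import CrossBasisSpec, SplineSpec, build_cross_basis, default_lag_spec

__all__ = [
    "ClusterAssignment",
    "ecdf_features",
    "default_grid",
    "ward_cluster",
    "fit_group_model",
]


@dataclass
class ClusterAssignment:
    """City -> cluster mapping plus the agglomeration record."""

    assignments: dict[str, int]  # city_id -> cluster in 1..k
    k: int
    feature_grid: np.ndarray
    linkage_heights: np.ndarray  # merge heights along the agglomeration

    def cities_in(self, cluster: int) -> list[str]:
        return sorted(c for c, g in self.assignments.items() if g == cluster)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignments.items()), columns=["city_id", "cluster"]
        )


def ecdf_features(temps: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical CDF of a city's daily temperatures on a common grid."""
    x = np.sort(np.asarray(temps, dtype=float))
    if x.size == 0:
        raise ValueError("empty temperature series")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (np.diff(grid) <= 0).any():
        raise ValueError("grid must be 1-D and strictly ascending")
    return np.searchsorted(x, grid, side="right") / x.size


def default_grid(series_list, step: float = 0.5) -> np.ndarray:
    """0.5-degree grid spanning the pooled min-max across all cities."""
    lo = min(float(np.min(s.temp_c)) for s in series_list)
    hi = max(float(np.max(s.temp_c)) for s in series_list)
    return np.arange(np.floor(lo / step) * step, np.ceil(hi / step) * step + step / 2, step)


def ward_cluster(
    features: np.ndarray, k: int, city_ids: list[str], grid: np.ndarray
) -> ClusterAssignment:
    """Ward minimum-variance hierarchical clustering, tree cut at k clusters.

    Cities are processed in lexicographic city_id order so the assignment is
    invariant to input order; cluster labels 1..k follow the order in which
    each cluster's first (lexicographically smallest) city appears.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if len(city_ids) != n:
        raise ValueError("one city_id per feature row required")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    order = np.argsort(np.asarray(city_ids, dtype=object))
    feats = features[order]
    ids_sorted = [city_ids[i] for i in order]
    Z = hierarchy.linkage(feats, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # canonical labels: 1..k in order of first appearance over sorted city ids
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    assignments = {cid: relabel[lab] for cid, lab in zip(ids_sorted, raw)}
    return ClusterAssignment(
        assignments=assignments,
        k=k,
        feature_grid=np.asarray(grid, dtype=float),
        linkage_heights=Z[:, 2].copy(),
    )


def fit_group_model(
    series_list,
    outcome: str = "deaths_all",
    crossbasis_spec: CrossBasisSpec | None = None,
    knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0),
    max_lag: int = 21,
    **fit_kwargs,
) -> tuple[FirstStageFit, CrossBasisSpec]:
    """One conditional Poisson fit for a cluster of cities.

    Exposure knots come from the pooled within-cluster temperature
    distribution unless an explicit ``crossbasis_spec`` is given.  Strata are
    city x year x month x day-of-week; each city's burn-in days are dropped.
    """
    if not series_list:
        raise ValueError("empty cluster")
    series_list = sorted(series_list, key=lambda s: s.city_id)
    pooled = np.concatenate([s.temp_c for s in series_list])
    if crossbasis_spec is None:
        crossbasis_spec = CrossBasisSpec(
            SplineSpec.from_percentiles(pooled, knot_percentiles),
            default_lag_spec(max_lag),
            max_lag,
        )
    X_parts, y_parts, off_parts, strata_parts = [], [], [], []
    for s in series_list:
        cb = build_cross_basis(s.temp_c, crossbasis_spec)
        keep = slice(crossbasis_spec.max_lag, None)
        X_parts.append(cb.matrix[keep])
        y_parts.append(s.deaths[outcome].to_numpy(dtype=float)[keep])
        off_parts.append(s.population_offset()[keep])
        strata_parts.append(make_strata(s.dates, np.repeat(s.city_id, len(s.dates)))[keep])
    fit = fit_from_arrays(
        np.vstack(X_parts),
        np.concatenate(y_parts),
        np.concatenate(off_parts),
        np.concatenate(strata_parts),
        city_id="|".join(s.city_id for s in series_list),
        **fit_kwargs,
    )
    return fit, crossbasis_spec
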