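"""End-to-end orchestration: simulate -> fit -> pool -> summarise -> cluster.

The pipeline is fully deterministic given a master seed: the seed fans out to
the simulator and to the Monte Carlo CI draws through
``numpy.random.SeedSequence``.  Each run writes delimited-text artifacts plus
a JSON manifest recording the configuration and derived seeds.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import default_grid, ecdf_features, fit_group_model, ward_cluster
from .first_stage import fit_conditional_poisson
from .risk import RiskSummary, pooled_edf, summaries_to_frame, summarize_city
from .second_stage import (
    MetaModel,
    blup,
    build_meta_predictors,
    fit_meta_regression,
    pooled_curve,
)
from .splines import (
    CrossBasisSpec,
    ReducedCurve,
    SplineSpec,
    build_cross_basis,
    curve_to_dict,
    default_lag_spec,
    reduce_to_overall,
)
from .synthetic import DailyCitySeries, default_template, simulate_study, write_study

logger = logging.getLogger("tempmort")

__all__ = ["RunConfig", "StudyResult", "run_two_stage", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full run; defaults follow the reference analysis."""

    outdir: str = "tempmort_run"
    n_cities: int = 20
    n_years: int = 3
    heterogeneity: float = 0.01
    master_seed: int = 0
    knot_percentiles: tuple[float, ...] = (10.0, 75.0, 90.0)
    max_lag: int = 21
    extreme_percentiles: tuple[float, float] = (5.0, 95.0)
    slope_percentiles: tuple[float, float, float, float] = (1.0, 5.0, 95.0, 99.0)
    n_draws: int = 1000
    country_merge: dict[str, str] = field(default_factory=dict)
    cluster_k: int = 3
    outcome: str = "deaths_all"
    cause_outcomes: tuple[str, ...] = ("deaths_cvd", "deaths_resp")

    def __post_init__(self) -> None:
        if list(self.extreme_percentiles) != sorted(self.extreme_percentiles):
            raise ValueError("extreme_percentiles must be ordered")
        if list(self.slope_percentiles) != sorted(self.slope_percentiles):
            raise ValueError("slope_percentiles must be ordered")
        if list(self.knot_percentiles) != sorted(self.knot_percentiles):
            raise ValueError("knot_percentiles must be ordered")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("knot_percentiles", "extreme_percentiles", "slope_percentiles",
                    "cause_outcomes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)


@dataclass
class StudyResult:
    """In-memory results of the two-stage analysis of one study."""

    series: list[DailyCitySeries]
    fits: list
    reduced_curves: list[ReducedCurve]
    predictors: pd.DataFrame
    meta: MetaModel
    smoothed: list[ReducedCurve]
    summaries: list[RiskSummary]
    pooled: ReducedCurve
    pooled_summary: RiskSummary | None


def _seed_for(master_seed: int, label: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the master seed."""
    digest = zlib.crc32(label.encode())  # stable across processes, unlike hash()
    ss = np.random.SeedSequence([master_seed, digest])
    return int(ss.generate_state(1)[0] % (2**31))


class _PooledSeries:
    """Study-wide pseudo-series used only to summarise the pooled curve."""

    def __init__(self, series_list: list[DailyCitySeries]):
        self.city_id = "pooled"
        self.temp_c = np.concatenate([s.temp_c for s in series_list])
        self.deaths = pd.concat([s.deaths for s in series_list], ignore_index=True)


def run_two_stage(
    series_list: list[DailyCitySeries],
    config: RunConfig | None = None,
) -> StudyResult:
    """First stage, meta-regression, BLUP smoothing and risk summaries.

    Each city gets its own exposure spline (knots at the configured
    percentiles of its observed temperatures plus min/max boundaries); reduced
    curves are initially centred at the city median temperature and re-centred
    at the estimated MMT inside the summaries.  The pooled curve is the
    fixed-effects prediction at the sample-mean continuous meta-predictors
    averaged over the observed country mix, evaluated on an exposure spline
    with across-city average knots.
    """
    config = config or RunConfig()
    lag_spec = default_lag_spec(config.max_lag)
    fits, curves = [], []
    for s in series_list:
        exp_spec = SplineSpec.from_percentiles(s.temp_c, config.knot_percentiles)
        cb_spec = CrossBasisSpec(exp_spec, lag_spec, config.max_lag)
        cb = build_cross_basis(s.temp_c, cb_spec)
        fit = fit_conditional_poisson(s, cb, outcome=config.outcome)
        logger.info("first stage %s: %d strata (%d dropped), dispersion %.2f",
                    s.city_id, fit.n_strata_used, fit.n_strata_dropped, fit.dispersion)
        curve = reduce_to_overall(fit.coef, fit.vcov, cb_spec,
                                  ref_temp=float(np.median(s.temp_c)), city_id=s.city_id)
        fits.append(fit)
        curves.append(curve)

    predictors = build_meta_predictors(series_list, config.country_merge)
    meta = fit_meta_regression(curves, predictors)
    logger.info("meta-regression: %d cities, REML loglik %.2f, converged=%s",
                meta.n_cities, meta.restricted_loglik, meta.converged)

    smoothed = []
    for curve, (_, row) in zip(curves, predictors.iterrows()):
        u = meta.design_row(row["median_temp"], row["temp_range"], row["country"])
        smoothed.append(blup(meta, curve, u).curve)

    summaries = []
    for s, curve in zip(series_list, smoothed):
        seed = _seed_for(config.master_seed, f"mc:{s.city_id}")
        summaries.append(summarize_city(curve, s, outcome=config.outcome,
                                        n_draws=config.n_draws, seed=seed))

    # pooled curve at the average meta-predictor point / observed country mix
    u_mean = np.array([1.0, predictors["median_temp"].mean(), predictors["temp_range"].mean()])
    mix = predictors["country"].value_counts(normalize=True)
    u_mean = np.concatenate([u_mean, [mix.get(lvl, 0.0) for lvl in meta.country_levels[1:]]])
    mean_boundaries = np.mean([c.exposure_spec.boundary_knots for c in curves], axis=0)
    mean_internal = np.mean([c.exposure_spec.internal_knots for c in curves], axis=0)
    pooled_spec = SplineSpec(tuple(mean_boundaries), tuple(mean_internal))
    pooled = pooled_curve(meta, u_mean, pooled_spec,
                          ref_temp=float(predictors["median_temp"].mean()))
    pooled_series = _PooledSeries(series_list)
    pooled_summary = summarize_city(
        pooled, pooled_series, outcome=config.outcome, n_draws=config.n_draws,
        seed=_seed_for(config.master_seed, "mc:pooled"),
    )
    return StudyResult(series_list, fits, curves, predictors, meta, smoothed,
                       summaries, pooled, pooled_summary)


def run_pipeline(config: RunConfig, series_list: list[DailyCitySeries] | None = None) -> Path:
    """Full run with artifacts: simulate (unless given data), analyse, cluster.

    Returns the run directory.  Partial outputs are retained if a stage
    fails; the failing stage is named in the raised error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {**asdict(config)},
        "package_version": __version__,
        "stages": {},
    }

    stage = "simulate"
    try:
        if series_list is None:
            template = default_template(n_years=config.n_years)
            series_list, scenarios = simulate_study(
                config.n_cities, template, heterogeneity=config.heterogeneity,
                master_seed=_seed_for(config.master_seed, "simulate"),
            )
            write_study(series_list, scenarios, outdir / "data")
        manifest["stages"]["simulate"] = {"n_cities": len(series_list)}

        stage = "two_stage"
        result = run_two_stage(series_list, config)
        fit_records = [
            {"city_id": f.city_id, "coef": f.coef.tolist(), "vcov": f.vcov.tolist(),
             "n_strata_used": f.n_strata_used, "n_strata_dropped": f.n_strata_dropped,
             "n_days_used": f.n_days_used, "converged": f.converged,
             "dispersion": f.dispersion}
            for f in result.fits
        ]
        (outdir / "first_stage_fits.json").write_text(json.dumps(fit_records))
        (outdir / "meta_model.json").write_text(json.dumps({
            "fixed_effects": result.meta.fixed_effects.tolist(),
            "psi": result.meta.psi.tolist(),
            "predictor_names": result.meta.predictor_names,
            "country_levels": result.meta.country_levels,
            "restricted_loglik": result.meta.restricted_loglik,
            "converged": result.meta.converged,
        }, indent=1))
        pd.DataFrame([
            {"city_id": c.city_id, "ref_temp": c.ref_temp,
             **{f"coef{i}": v for i, v in enumerate(c.coef)},
             **{f"vcov{i}{j}": c.vcov[i, j] for i in range(len(c.coef))
                for j in range(len(c.coef))}}
            for c in result.smoothed
        ]).to_csv(outdir / "smoothed_curves.csv", index=False)
        summaries_to_frame(result.summaries).to_csv(outdir / "risk_summaries.csv", index=False)
        (outdir / "pooled_curve.json").write_text(json.dumps(curve_to_dict(result.pooled)))
        manifest["stages"]["two_stage"] = {
            "n_fits": len(result.fits),
            "pooled_edf_total": pooled_edf(result.summaries, "total"),
            "pooled_edf_heat": pooled_edf(result.summaries, "heat"),
            "pooled_edf_cold": pooled_edf(result.summaries, "cold"),
        }

        stage = "cluster"
        grid = default_grid(series_list)
        feats = np.stack([ecdf_features(s.temp_c, grid) for s in series_list])
        assignment = ward_cluster(feats, config.cluster_k,
                                  [s.city_id for s in series_list], grid)
        assignment.to_frame().to_csv(outdir / "cluster_assignments.csv", index=False)
        by_id = {s.city_id: s for s in series_list}
        group_records = []
        for cluster in range(1, config.cluster_k + 1):
            members = [by_id[c] for c in assignment.cities_in(cluster)]
            for outcome in config.cause_outcomes:
                fit, spec = fit_group_model(members, outcome=outcome,
                                            knot_percentiles=config.knot_percentiles,
                                            max_lag=config.max_lag)
                group_records.append({
                    "cluster": cluster, "outcome": outcome, "coef": fit.coef.tolist(),
                    "vcov": fit.vcov.tolist(), "n_strata_used": fit.n_strata_used,
                    "spec": spec.to_dict(),
                })
        (outdir / "group_fits.json").write_text(json.dumps(group_records))
        manifest["stages"]["cluster"] = {"k": config.cluster_k,
                                         "n_group_fits": len(group_records)}
    except Exception as err:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {err}") from err

    manifest["python"] = sys.version.split()[0]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
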