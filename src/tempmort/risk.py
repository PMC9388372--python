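"""Risk summaries from smoothed exposure-response curves.

All summaries are computed from a lag-cumulated curve re-centred at the
minimum mortality temperature (MMT), the observed daily temperature at which
the curve attains its minimum:

* relative risks at tail percentiles of the city's temperature distribution;
* "extreme slopes": the log-RR difference between the 99th and 95th (heat) or
  1st and 5th (cold) percentiles divided by the corresponding temperature
  gap, expressed as RR per 1 degree C;
* excess death fractions (EDF): for each day, the attributable fraction
  AF_t = 1 - exp(-logRR(x_t)); attributable deaths are AF_t * n_t summed over
  the component's days (heat: above MMT, cold: below MMT, extreme heat/cold:
  beyond the 95th/5th percentile), and the EDF is that sum as a percentage of
  all deaths.

Confidence intervals are empirical quantiles over Monte Carlo draws of the
curve coefficients from N(coef, vcov); the MMT is held fixed at its point
estimate across draws.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .splines import ReducedCurve

__all__ = [
    "RiskSummary",
    "find_mmt",
    "attributable_fraction",
    "edf_confidence",
    "extreme_slope",
    "rr_at_percentile",
    "summarize_city",
    "pooled_edf",
]

COMPONENTS = ("total", "heat", "cold", "extreme_heat", "extreme_cold")


@dataclass
class RiskSummary:
    """Per-city headline numbers: MMT, tail RRs, extreme slopes, EDFs."""

    city_id: str
    mmt: float
    rr_p95: float
    rr_p95_lo: float
    rr_p95_hi: float
    rr_p5: float
    rr_p5_lo: float
    rr_p5_hi: float
    slope_heat_rr: float
    slope_heat_lo: float
    slope_heat_hi: float
    slope_cold_rr: float
    slope_cold_lo: float
    slope_cold_hi: float
    edf_total: float
    edf_total_lo: float
    edf_total_hi: float
    edf_heat: float
    edf_heat_lo: float
    edf_heat_hi: float
    edf_cold: float
    edf_cold_lo: float
    edf_cold_hi: float
    edf_extreme_heat: float
    edf_extreme_heat_lo: float
    edf_extreme_heat_hi: float
    edf_extreme_cold: float
    edf_extreme_cold_lo: float
    edf_extreme_cold_hi: float
    attributable_deaths_total: float
    attributable_deaths_heat: float
    attributable_deaths_cold: float
    total_deaths: float

    def to_row(self) -> dict:
        return asdict(self)


def find_mmt(curve: ReducedCurve, observed_temps: np.ndarray) -> float:
    """Observed temperature minimising the curve's predicted log-RR.

    Ties (within floating-point exactness) are broken toward the median
    observed temperature.
    """
    temps = np.unique(np.asarray(observed_temps, dtype=float))
    if temps.size == 0:
        raise ValueError("no observed temperatures")
    log_rr, _ = curve.predict(temps)
    best = log_rr.min()
    candidates = temps[log_rr == best]
    med = np.median(np.asarray(observed_temps, dtype=float))
    return float(candidates[np.argmin(np.abs(candidates - med))])


def _component_mask(temps: np.ndarray, mmt: float, p5: float, p95: float, component: str):
    if component == "total":
        return temps != mmt
    if component == "heat":
        return temps > mmt
    if component == "cold":
        return temps < mmt
    if component == "extreme_heat":
        return temps >= p95
    if component == "extreme_cold":
        return temps <= p5
    raise ValueError(f"unknown component {component!r}")


def _check_recentred(curve: ReducedCurve, mmt: float) -> None:
    log_rr, _ = curve.predict(np.array([mmt]))
    if abs(log_rr[0]) > 1e-9:
        raise ValueError("curve must be re-centred at the MMT before attribution")


def attributable_fraction(
    curve: ReducedCurve,
    series,
    component: str = "total",
    outcome: str = "deaths_all",
    mmt: float | None = None,
) -> tuple[float, float]:
    """Attributable deaths and excess death fraction (%) for one component.

    The curve must already be re-centred at the MMT (``curve.ref_temp``); the
    extreme components use the 5th/95th percentiles of the city's observed
    daily temperatures.
    """
    mmt = curve.ref_temp if mmt is None else mmt
    _check_recentred(curve, mmt)
    temps = np.asarray(series.temp_c, dtype=float)
    deaths = series.deaths[outcome].to_numpy(dtype=float)
    p5, p95 = np.percentile(temps, [5, 95])
    mask = _component_mask(temps, mmt, p5, p95, component)
    log_rr, _ = curve.predict(temps)
    af = 1.0 - np.exp(-log_rr)
    attributable = float(af[mask] @ deaths[mask])
    total = float(deaths.sum())
    return attributable, 100.0 * attributable / total


def _draw_coefs(curve: ReducedCurve, n_draws: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    vc = 0.5 * (curve.vcov + curve.vcov.T)
    w, V = np.linalg.eigh(vc)
    if (w < -1e-8 * max(w.max(), 1.0)).any():
        raise ValueError("degenerate (indefinite) vcov for Monte Carlo draws")
    A = V * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n_draws, curve.coef.size))
    return curve.coef + z @ A.T


def _edf_draws(
    curve: ReducedCurve, series, component: str, outcome: str, draws: np.ndarray
) -> np.ndarray:
    """EDF per coefficient draw, curve centred at the fixed point-estimate MMT."""
    temps = np.asarray(series.temp_c, dtype=float)
    deaths = series.deaths[outcome].to_numpy(dtype=float)
    p5, p95 = np.percentile(temps, [5, 95])
    mask = _component_mask(temps, curve.ref_temp, p5, p95, component)
    Bd = curve.centred_basis(temps[mask])
    log_rr = Bd @ draws.T  # days x draws
    af = 1.0 - np.exp(-log_rr)
    return 100.0 * (deaths[mask] @ af) / deaths.sum()


def edf_confidence(
    curve: ReducedCurve,
    series,
    component: str = "total",
    outcome: str = "deaths_all",
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical 95% CI of the EDF over Monte Carlo coefficient draws."""
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    _check_recentred(curve, curve.ref_temp)
    draws = _draw_coefs(curve, n_draws, seed)
    vals = _edf_draws(curve, series, component, outcome, draws)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def extreme_slope(
    curve: ReducedCurve,
    observed_temps: np.ndarray,
    side: str = "heat",
    draws: np.ndarray | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """RR per 1 degree C in the temperature tail, with a Monte Carlo 95% CI.

    Heat: (logRR at P99 - logRR at P95) / (T99 - T95), per 1 C increase.
    Cold: (logRR at P1 - logRR at P5) / (T5 - T1), per 1 C decrease.
    """
    temps = np.asarray(observed_temps, dtype=float)
    if side == "heat":
        t_a, t_b = np.percentile(temps, [99, 95])
        gap = t_a - t_b
    elif side == "cold":
        t_a, t_b = np.percentile(temps, [1, 5])
        gap = t_b - t_a
    else:
        raise ValueError("side must be 'heat' or 'cold'")
    if gap <= 0:
        raise ValueError(f"degenerate temperature distribution: zero {side} tail gap")
    Bd = curve.centred_basis(np.array([t_a, t_b]))
    contrast = (Bd[0] - Bd[1]) / gap
    point = float(np.exp(contrast @ curve.coef))
    if draws is None:
        draws = _draw_coefs(curve, n_draws, seed)
    vals = np.exp(draws @ contrast)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return point, float(lo), float(hi)


def rr_at_percentile(
    curve: ReducedCurve, observed_temps: np.ndarray, p: float
) -> tuple[float, float, float]:
    """RR (vs the curve's reference) at an empirical temperature percentile.

    CI by the delta method on the log scale: exp(logRR +- 1.96 se).
    """
    t = np.percentile(np.asarray(observed_temps, dtype=float), p)
    log_rr, se = curve.predict(np.array([t]))
    return (
        float(np.exp(log_rr[0])),
        float(np.exp(log_rr[0] - 1.96 * se[0])),
        float(np.exp(log_rr[0] + 1.96 * se[0])),
    )


def summarize_city(
    smoothed_curve: ReducedCurve,
    series,
    outcome: str = "deaths_all",
    n_draws: int = 1000,
    seed: int = 0,
) -> RiskSummary:
    """All headline summaries for one city from its smoothed curve.

    The curve is re-centred at the city's MMT; a single set of Monte Carlo
    coefficient draws is shared by every EDF and slope CI, so additivity
    (EDF_heat + EDF_cold = EDF_total) holds draw by draw.
    """
    temps = np.asarray(series.temp_c, dtype=float)
    mmt = find_mmt(smoothed_curve, temps)
    curve = smoothed_curve.recenter(mmt)
    draws = _draw_coefs(curve, n_draws, seed)

    edf: dict[str, tuple[float, float, float]] = {}
    attr: dict[str, float] = {}
    for comp in COMPONENTS:
        a, point = attributable_fraction(curve, series, comp, outcome)
        vals = _edf_draws(curve, series, comp, outcome, draws)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        edf[comp] = (point, float(lo), float(hi))
        attr[comp] = a

    sh = extreme_slope(curve, temps, "heat", draws=draws)
    sc = extreme_slope(curve, temps, "cold", draws=draws)
    r95 = rr_at_percentile(curve, temps, 95)
    r5 = rr_at_percentile(curve, temps, 5)
    return RiskSummary(
        city_id=series.city_id,
        mmt=mmt,
        rr_p95=r95[0], rr_p95_lo=r95[1], rr_p95_hi=r95[2],
        rr_p5=r5[0], rr_p5_lo=r5[1], rr_p5_hi=r5[2],
        slope_heat_rr=sh[0], slope_heat_lo=sh[1], slope_heat_hi=sh[2],
        slope_cold_rr=sc[0], slope_cold_lo=sc[1], slope_cold_hi=sc[2],
        edf_total=edf["total"][0], edf_total_lo=edf["total"][1], edf_total_hi=edf["total"][2],
        edf_heat=edf["heat"][0], edf_heat_lo=edf["heat"][1], edf_heat_hi=edf["heat"][2],
        edf_cold=edf["cold"][0], edf_cold_lo=edf["cold"][1], edf_cold_hi=edf["cold"][2],
        edf_extreme_heat=edf["extreme_heat"][0],
        edf_extreme_heat_lo=edf["extreme_heat"][1],
        edf_extreme_heat_hi=edf["extreme_heat"][2],
        edf_extreme_cold=edf["extreme_cold"][0],
        edf_extreme_cold_lo=edf["extreme_cold"][1],
        edf_extreme_cold_hi=edf["extreme_cold"][2],
        attributable_deaths_total=attr["total"],
        attributable_deaths_heat=attr["heat"],
        attributable_deaths_cold=attr["cold"],
        total_deaths=float(series.deaths[outcome].sum()),
    )


def pooled_edf(summaries: list[RiskSummary], component: str = "total") -> float:
    """Study-level EDF: summed attributable deaths over summed total deaths (%).

    Death-weighted by construction; never an average of city EDFs.
    """
    key = {"total": "attributable_deaths_total", "heat": "attributable_deaths_heat",
           "cold": "attributable_deaths_cold"}[component]
    num = sum(getattr(s, key) for s in summaries)
    den = sum(s.total_deaths for s in summaries)
    return 100.0 * num / den


def summaries_to_frame(summaries: list[RiskSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
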