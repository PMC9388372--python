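"""MMT search, attributable fractions, Monte Carlo CIs, extreme slopes."""

import numpy as np
import pandas as pd
import pytest

import tempmort as tm
from tempmort.risk import (
    attributable_fraction,
    edf_confidence,
    extreme_slope,
    find_mmt,
    pooled_edf,
    rr_at_percentile,
    summarize_city,
)

from conftest import linear_curve


class TinySeries:
    """Hand-built series for arithmetic checks."""

    def __init__(self, temps, deaths):
        self.city_id = "tiny"
        self.temp_c = np.asarray(temps, dtype=float)
        self.deaths = pd.DataFrame({"deaths_all": np.asarray(deaths)})


def v_curve(mmt, heat=0.05, cold=0.03, lo=0.0, hi=40.0):
    """A smooth convex curve with minimum exactly at ``mmt``: quadratic-ish

    via the spline basis fitted to a V shape (used where only the argmin
    location matters)."""
    spec = tm.SplineSpec((lo, hi), (lo + (hi - lo) * 0.25, mmt, lo + (hi - lo) * 0.9))
    x = np.linspace(lo, hi, 400)
    target = heat * np.maximum(x - mmt, 0) + cold * np.maximum(mmt - x, 0)
    B = tm.natural_cubic_basis(x, spec)
    Bc = B - tm.natural_cubic_basis(np.array([mmt]), spec)
    coef = np.linalg.lstsq(Bc, target, rcond=None)[0]
    return tm.ReducedCurve(coef, 1e-6 * np.eye(spec.df), spec, mmt)


def test_find_mmt_returns_observed_vertex():
    curve = v_curve(mmt=22.0)
    temps = np.array([10.0, 15.0, 22.0, 28.0, 35.0])
    assert find_mmt(curve, temps) == 22.0


def test_find_mmt_monotone_decreasing_returns_max_observed():
    curve = linear_curve(slope=-0.05, ref=20.0)
    temps = np.array([5.0, 12.0, 19.0, 33.0])
    assert find_mmt(curve, temps) == 33.0


def test_find_mmt_matches_exhaustive_reimplementation(reduced_curve, small_city):
    _, series = small_city
    mmt = find_mmt(reduced_curve, series.temp_c)
    # independent brute force over every observed temperature
    temps = np.asarray(series.temp_c)
    vals = np.array([reduced_curve.predict(np.array([t]))[0][0] for t in np.unique(temps)])
    uniq = np.unique(temps)
    best = uniq[vals == vals.min()]
    med = np.median(temps)
    expected = best[np.argmin(np.abs(best - med))]
    assert mmt == expected


def test_flat_curve_gives_zero_edf():
    curve = linear_curve(slope=0.0, ref=20.0)
    series = TinySeries(np.linspace(5, 35, 200), np.full(200, 5))
    for comp in ("total", "heat", "cold", "extreme_heat", "extreme_cold"):
        attributable, edf = attributable_fraction(curve, series, comp)
        assert attributable == 0.0 and edf == 0.0


def test_single_hot_day_arithmetic():
    """One day at RR=2 with 10 deaths among 1,000 total: 5 attributable, 0.5%."""
    mmt = 20.0
    hot = 30.0
    slope = np.log(2.0) / (hot - mmt)
    curve = linear_curve(slope=slope, ref=mmt)
    temps = np.concatenate([np.full(99, mmt), [hot]])
    deaths = np.concatenate([np.full(99, 10), [10]])
    series = TinySeries(temps, deaths)
    attributable, edf = attributable_fraction(curve, series, "heat")
    assert abs(attributable - 5.0) < 1e-10
    assert abs(edf - 0.5) < 1e-10


def test_attribution_matches_day_by_day_loop(reduced_curve, small_city):
    _, series = small_city
    mmt = find_mmt(reduced_curve, series.temp_c)
    curve = reduced_curve.recenter(mmt)
    p5, p95 = np.percentile(series.temp_c, [5, 95])
    deaths = series.deaths["deaths_all"].to_numpy(float)
    total = deaths.sum()
    oracle = {k: 0.0 for k in ("total", "heat", "cold", "extreme_heat", "extreme_cold")}
    for t, n in zip(series.temp_c, deaths):
        af = 1.0 - np.exp(-curve.predict(np.array([t]))[0][0])
        if t != mmt:
            oracle["total"] += af * n
        if t > mmt:
            oracle["heat"] += af * n
        if t < mmt:
            oracle["cold"] += af * n
        if t >= p95:
            oracle["extreme_heat"] += af * n
        if t <= p5:
            oracle["extreme_cold"] += af * n
    for comp, expected in oracle.items():
        attributable, edf = attributable_fraction(curve, series, comp)
        assert abs(attributable - expected) < 1e-12 * max(1.0, abs(expected))
        assert abs(edf - 100 * expected / total) < 1e-12
    heat = attributable_fraction(curve, series, "heat")[1]
    cold = attributable_fraction(curve, series, "cold")[1]
    tot = attributable_fraction(curve, series, "total")[1]
    assert abs(heat + cold - tot) < 1e-10


def test_attribution_requires_recentred_curve(reduced_curve, small_city):
    _, series = small_city
    off_centre = reduced_curve.recenter(reduced_curve.ref_temp + 3.0)
    with pytest.raises(ValueError, match="re-centred"):
        attributable_fraction(off_centre, series, "total",
                              mmt=reduced_curve.ref_temp)


def test_edf_ci_collapses_when_vcov_zero(small_city):
    _, series = small_city
    curve = linear_curve(slope=0.02, ref=float(np.median(series.temp_c)), var=0.0)
    point = attributable_fraction(curve, series, "heat")[1]
    lo, hi = edf_confidence(curve, series, "heat", n_draws=500, seed=1)
    assert abs(lo - point) < 1e-12 and abs(hi - point) < 1e-12


def test_edf_ci_deterministic_under_fixed_seed(reduced_curve, small_city):
    _, series = small_city
    curve = reduced_curve.recenter(find_mmt(reduced_curve, series.temp_c))
    a = edf_confidence(curve, series, "total", n_draws=400, seed=9)
    b = edf_confidence(curve, series, "total", n_draws=400, seed=9)
    assert a == b


def test_extreme_slope_arithmetic_from_definition():
    """logRR 1.2 at P99, 1.1 at P95, 2 degrees apart -> RR/1C ~ 1.0445."""
    temps = np.concatenate([np.linspace(0, 28, 950), np.linspace(28, 30, 50)])
    t95, t99 = np.percentile(temps, [95, 99])
    gap = t99 - t95
    slope = (np.log(1.2) - np.log(1.1)) / gap
    ref = t95 - np.log(1.1) / slope  # so that logRR(t95) = log 1.1 exactly
    curve = linear_curve(slope=slope, ref=ref)
    rr, _, _ = extreme_slope(curve, temps, "heat", n_draws=100, seed=0)
    assert abs(rr - np.exp((np.log(1.2) - np.log(1.1)) / gap)) < 1e-10


def test_flat_curve_slopes_are_one():
    temps = np.linspace(0, 30, 500)
    curve = linear_curve(slope=0.0, ref=15.0)
    assert extreme_slope(curve, temps, "heat", n_draws=100, seed=0)[0] == 1.0
    assert extreme_slope(curve, temps, "cold", n_draws=100, seed=0)[0] == 1.0


def test_cold_slope_is_rr_per_degree_decrease():
    temps = np.linspace(0, 30, 500)
    curve = linear_curve(slope=-0.03, ref=15.0)  # risk rises toward cold
    rr, _, _ = extreme_slope(curve, temps, "cold", n_draws=100, seed=0)
    assert abs(rr - np.exp(0.03)) < 1e-10


def test_degenerate_tail_gap_rejected():
    curve = linear_curve(slope=0.01, ref=15.0)
    with pytest.raises(ValueError, match="gap"):
        extreme_slope(curve, np.full(100, 15.0), "heat")


def test_rr_at_percentile_identities(reduced_curve, small_city):
    _, series = small_city
    mmt = find_mmt(reduced_curve, series.temp_c)
    curve = reduced_curve.recenter(mmt)
    # at the MMT's own percentile the RR is 1
    p_mmt = 100.0 * (series.temp_c <= mmt).mean()
    t = np.percentile(series.temp_c, p_mmt)
    if abs(t - mmt) < 1e-9:
        rr, lo, hi = rr_at_percentile(curve, series.temp_c, p_mmt)
        assert abs(rr - 1.0) < 1e-12
    # invariance to the original centering temperature
    other = reduced_curve.recenter(reduced_curve.ref_temp - 5.0).recenter(mmt)
    for p in (5.0, 95.0):
        a = rr_at_percentile(curve, series.temp_c, p)
        b = rr_at_percentile(other, series.temp_c, p)
        assert np.allclose(a, b, atol=1e-12)
    # composition with predict_curve
    t95 = np.percentile(series.temp_c, 95)
    log_rr, _ = curve.predict(np.array([t95]))
    assert abs(rr_at_percentile(curve, series.temp_c, 95)[0] - np.exp(log_rr[0])) < 1e-12


def test_summary_invariants_and_pooled_aggregation(small_city, reduced_curve):
    _, series = small_city
    summary = summarize_city(reduced_curve, series, n_draws=300, seed=4)
    assert abs(summary.edf_heat + summary.edf_cold - summary.edf_total) < 1e-10
    p5, p95 = np.percentile(series.temp_c, [5, 95])
    if p95 > summary.mmt:
        assert summary.edf_extreme_heat <= summary.edf_heat + 1e-12
    if p5 < summary.mmt:
        assert summary.edf_extreme_cold <= summary.edf_cold + 1e-12
    assert summary.edf_total < 100
    # study-level EDF is death-weighted, not an average of city EDFs
    pooled = pooled_edf([summary, summary], "total")
    assert abs(pooled - summary.edf_total) < 1e-12
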