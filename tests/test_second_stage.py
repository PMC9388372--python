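"""Multivariate meta-regression: REML, pooling identities, BLUP behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import tempmort as tm
from tempmort.second_stage import blup, fit_meta_regression, pooled_curve

SPEC = tm.SplineSpec((0.0, 30.0), (5.0, 15.0, 25.0))


def make_curves(Y, S_list):
    return [tm.ReducedCurve(y, S, SPEC, 15.0, f"c{i}")
            for i, (y, S) in enumerate(zip(Y, S_list))]


def intercept_predictors(n, **cols):
    base = {"city_id": [f"c{i}" for i in range(n)],
            "median_temp": np.zeros(n), "temp_range": np.zeros(n),
            "country": ["A"] * n}
    base.update(cols)
    return pd.DataFrame(base)


def test_identical_cities_with_zero_psi_return_common_coef():
    y = np.array([0.2, -0.1, 0.05, 0.3])
    curves = make_curves([y] * 6, [0.01 * np.eye(4)] * 6)
    m = fit_meta_regression(curves, intercept_predictors(6), intercept_only=True,
                            fix_psi=np.zeros((4, 4)))
    assert np.allclose(m.fixed_effects[0], y, atol=1e-12)


def test_zero_psi_equal_vcov_pooling_is_inverse_variance_mean():
    rng = np.random.default_rng(3)
    S = 0.02 * np.eye(4) + 0.005
    Y = rng.normal(0, 0.1, (8, 4))
    curves = make_curves(Y, [S] * 8)
    m = fit_meta_regression(curves, intercept_predictors(8), intercept_only=True,
                            fix_psi=np.zeros((4, 4)))
    # equal within-city covariances: the GLS solution is the plain mean
    assert np.max(np.abs(m.fixed_effects[0] - Y.mean(axis=0))) < 1e-8


def test_reml_matches_independent_direct_optimizer_on_five_cities():
    """Oracle: direct Nelder-Mead on the unprofiled restricted likelihood,
    parameterising psi via a matrix log (symmetric-eigh), written without any
    of the package's meta-regression internals."""
    rng = np.random.default_rng(8)
    n, k = 5, 4
    mu = np.array([0.1, -0.2, 0.3, 0.0])
    S_list = []
    Y = np.empty((n, k))
    for i in range(n):
        A = rng.normal(0, 0.02, (k, k + 2))
        S = A @ A.T + 0.01 * np.eye(k)
        S_list.append(S)
        Y[i] = mu + rng.multivariate_normal(np.zeros(k), 0.03**2 * np.eye(k) + S)

    def oracle_reml(params):
        # psi = expm of a symmetric matrix built from the 10 free parameters
        M = np.zeros((k, k))
        M[np.triu_indices(k)] = params
        M = M + np.triu(M, 1).T
        w, V = np.linalg.eigh(M)
        psi = (V * np.exp(w)) @ V.T
        Vis = [S + psi for S in S_list]
        Wis = [np.linalg.inv(V_) for V_ in Vis]
        Wsum = sum(Wis)
        beta = np.linalg.solve(Wsum, sum(W @ y for W, y in zip(Wis, Y)))
        quad = sum((y - beta) @ W @ (y - beta) for W, y in zip(Wis, Y))
        logdets = sum(np.linalg.slogdet(V_)[1] for V_ in Vis)
        return 0.5 * (logdets + np.linalg.slogdet(Wsum)[1] + quad)

    m = fit_meta_regression(make_curves(Y, S_list), intercept_predictors(n),
                            intercept_only=True)

    def params_of(psi):
        w, V = np.linalg.eigh(psi)
        M = (V * np.log(np.maximum(w, 1e-12))) @ V.T
        return M[np.triu_indices(k)]

    # the oracle's restricted likelihood agrees with the reported value at
    # the fitted psi ...
    assert abs(oracle_reml(params_of(m.psi)) + m.restricted_loglik) < 1e-8
    # ... the fitted psi is a local optimum of the oracle objective ...
    rng2 = np.random.default_rng(0)
    base = oracle_reml(params_of(m.psi))
    for _ in range(20):
        perturbed = params_of(m.psi) + rng2.normal(0, 1e-3, k * (k + 1) // 2)
        assert oracle_reml(perturbed) >= base - 1e-7
    # ... and an independent optimizer started elsewhere finds no better one
    x0 = np.zeros(k * (k + 1) // 2)
    x0[[0, 4, 7, 9]] = np.log(0.03**2)  # diagonal entries of the matrix log
    res = optimize.minimize(oracle_reml, x0, method="Powell",
                            options={"maxiter": 50000, "ftol": 1e-12})
    assert -res.fun <= m.restricted_loglik + 1e-6
    # the oracle's GLS fixed effects at the shared optimum match
    Wis = [np.linalg.inv(S + m.psi) for S in S_list]
    beta_oracle = np.linalg.solve(sum(Wis), sum(W @ y for W, y in zip(Wis, Y)))
    assert np.max(np.abs(beta_oracle - m.fixed_effects[0])) < 1e-8


def test_too_few_cities_rejected():
    curves = make_curves([np.zeros(4)] * 2, [np.eye(4)] * 2)
    with pytest.raises(ValueError, match="cities"):
        fit_meta_regression(curves, intercept_predictors(2), intercept_only=True)


def test_blup_limits_and_betweenness():
    rng = np.random.default_rng(5)
    Y = rng.normal(0, 0.1, (8, 4))
    S = [0.02 * np.eye(4)] * 8
    curves = make_curves(Y, S)
    # diagonal, well-conditioned psi makes the limits exact and satisfies the
    # betweenness precondition
    m = fit_meta_regression(curves, intercept_predictors(8), intercept_only=True,
                            fix_psi=np.diag([0.04, 0.03, 0.05, 0.02]))
    u = np.ones(1)
    mean = m.fixed_effects[0]

    tiny = tm.ReducedCurve(Y[0], 1e-14 * np.eye(4), SPEC, 15.0, "tiny")
    assert np.max(np.abs(blup(m, tiny, u).curve.coef - Y[0])) < 1e-6

    huge = tm.ReducedCurve(Y[0], 1e10 * np.eye(4), SPEC, 15.0, "huge")
    assert np.max(np.abs(blup(m, huge, u).curve.coef - mean)) < 1e-6

    # between-ness under diagonal psi and S_i
    for _ in range(10):
        y = rng.normal(0, 0.2, 4)
        c = tm.ReducedCurve(y, np.diag(rng.uniform(0.01, 0.1, 4)), SPEC, 15.0, "x")
        b = blup(m, c, u).curve.coef
        lo = np.minimum(y, mean) - 1e-12
        hi = np.maximum(y, mean) + 1e-12
        if np.allclose(np.diag(np.diag(m.psi)), m.psi, atol=1e-12):
            assert np.all(b >= lo) and np.all(b <= hi)


def test_blup_shrinkage_monotone_in_within_city_variance():
    rng = np.random.default_rng(6)
    Y = rng.normal(0, 0.1, (10, 4))
    curves = make_curves(Y, [0.01 * np.eye(4)] * 10)
    m = fit_meta_regression(curves, intercept_predictors(10), intercept_only=True)
    u = np.ones(1)
    mean = m.fixed_effects[0]
    psi_inv = np.linalg.inv(m.psi + 1e-12 * np.eye(4))
    y = Y[0]
    S0 = np.diag([0.01, 0.02, 0.005, 0.03])
    prev = None
    for lam in [1.0, 2.0, 5.0, 20.0, 100.0]:
        c = tm.ReducedCurve(y, lam * S0, SPEC, 15.0, "x")
        b = blup(m, c, u).curve.coef
        d = b - mean
        dist = float(d @ psi_inv @ d)
        if prev is not None:
            assert dist <= prev + 1e-10
        prev = dist


def test_smoothed_curves_near_identical_when_psi_tiny():
    rng = np.random.default_rng(9)
    Y = 0.1 + rng.normal(0, 0.001, (8, 4))
    curves = make_curves(Y, [0.05 * np.eye(4)] * 8)
    m = fit_meta_regression(curves, intercept_predictors(8), intercept_only=True)
    u = np.ones(1)
    blups = np.stack([blup(m, c, u).curve.coef for c in curves])
    assert np.max(blups.std(axis=0)) < 0.002


def test_blup_predictor_mismatch_rejected():
    curves = make_curves([np.zeros(4)] * 6, [np.eye(4)] * 6)
    m = fit_meta_regression(curves, intercept_predictors(6), intercept_only=True,
                            fix_psi=np.zeros((4, 4)))
    with pytest.raises(ValueError, match="predictor"):
        blup(m, curves[0], np.ones(3))


def test_pooled_curve_prediction_is_affine_in_predictors():
    rng = np.random.default_rng(11)
    n = 12
    pred = intercept_predictors(
        n,
        median_temp=rng.uniform(10, 25, n),
        temp_range=rng.uniform(10, 30, n),
        country=["A", "B"] * (n // 2),
    )
    Y = rng.normal(0, 0.05, (n, 4))
    curves = make_curves(Y, [0.01 * np.eye(4)] * n)
    m = fit_meta_regression(curves, pred)
    u1 = m.design_row(15.0, 20.0, "A")
    u2 = m.design_row(19.0, 24.0, "A")
    c1 = pooled_curve(m, u1, SPEC, 15.0)
    c2 = pooled_curve(m, u2, SPEC, 15.0)
    cmid = pooled_curve(m, (u1 + u2) / 2, SPEC, 15.0)
    assert np.allclose(cmid.coef, (c1.coef + c2.coef) / 2, atol=1e-12)


def test_pooled_curve_covariance_matches_monte_carlo():
    rng = np.random.default_rng(13)
    Y = rng.normal(0, 0.08, (10, 4))
    curves = make_curves(Y, [0.01 * np.eye(4)] * 10)
    m = fit_meta_regression(curves, intercept_predictors(10), intercept_only=True)
    c = pooled_curve(m, np.ones(1), SPEC, 15.0)
    draws = rng.multivariate_normal(np.zeros(4 * 1), m.vcov_fixed, size=100_000)
    mc = np.cov(draws.T)
    assert np.max(np.abs(mc - c.vcov)) < 0.02 * np.max(np.abs(c.vcov)) + 1e-5
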