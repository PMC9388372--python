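# Methods

## Model

Daily death counts `y_ct` in city `c` are modelled as Poisson with log link:

```
log E[y_ct] = offset_ct + alpha_{s(t)} + crossbasis(x_c, t) @ beta_c
```

where `offset_ct = log(annual population)`, `alpha_s` are intercepts for
strata `s = (year, month, day-of-week)`, and the cross-basis encodes a
bidimensional function of temperature and lag. The stratum intercepts are
never estimated: conditioning on the stratum death totals turns each stratum
into a multinomial over its days with probabilities
`p_i = exp(eta_i) / sum_j exp(eta_j)`, and the conditional maximum-likelihood
estimate of `beta_c` coincides with the fixed-effects Poisson estimate. The
offset is constant within a stratum (strata never span years), so it cancels
from the conditional likelihood; it is kept in the linear predictor for
generality.

### Cross-basis

- Temperature: natural cubic spline, boundary knots at the city's observed
  min/max, internal knots at its 10th/75th/90th percentiles
  (linear-interpolation quantiles); 4 columns, no intercept.
- Lag: natural cubic spline on 0-21 days with intercept and 3 internal knots
  equally spaced on the log(lag+1) scale; 5 columns. This lag layout is the
  convention of the two-stage multi-city literature and is configurable.
- Cross-basis = tensor product, 20 columns. Row `t` uses exposures
  `x_t ... x_{t-21}`; the first 21 days of each series are excluded from
  every likelihood (their exposure history is padded).

The natural spline basis is the truncated-power closed form, linear at and
beyond the boundary knots by construction. Basis dimension is always
(number of internal knots) + 1, plus 1 with intercept.

### Reduction and curves

Summing the fitted surface over integer lags 0..21 (daily data are discrete,
so a sum, not an integral) gives 4 reduced coefficients and their covariance.
A reduced curve predicts `logRR(x) = (b(x) - b(ref)) @ coef`; re-centering is
exact basis-difference algebra, so curves are first centred at the city
median temperature and re-centred at the MMT once estimated, without
approximation.

### Second stage

Reduced coefficient vectors are pooled by multivariate random-effects
meta-regression, `y_i ~ N(B' u_i, S_i + Psi)`, estimated by REML with the
fixed effects profiled out by GLS and `Psi` parameterised by its Cholesky
factor (log-diagonal), guaranteeing positive semidefiniteness. Optimisation
is BFGS from a method-of-moments start with a Nelder-Mead polish.
Meta-predictors: intercept, median observed daily temperature, temperature
range (max - min by default; IQR available), and country indicators (a
configurable merge map can pool small countries). BLUPs use
`K = Psi (Psi + S_i)^(-1)`; their conditional covariance combines
`Psi - K Psi` with propagated fixed-effect uncertainty
`(I-K) X V_B X' (I-K)'`.

The pooled ("overall") curve is the fixed-effects prediction at the sample
mean of the continuous meta-predictors averaged over the observed country
mix, evaluated on an exposure spline with across-city average knots, and
summarised against the pooled (concatenated) temperature distribution. The
pooling point is a package choice; predictions are affine in the predictors,
so other pooling points are one call away.

### Risk summaries

- MMT: argmin of the smoothed curve over the set of observed daily
  temperatures, ties broken toward the median. No percentile trimming is
  applied.
- EDF: per day, `AF_t = 1 - exp(-logRR(x_t))`; attributable deaths are
  `sum AF_t * n_t` over component days (heat: above MMT; cold: below;
  extreme: beyond the city's 5th/95th percentiles), as a percentage of all
  deaths. Heat and cold partition the off-MMT days, so
  EDF_heat + EDF_cold = EDF_total holds exactly, draw by draw.
- Extreme slopes: `(logRR(T99) - logRR(T95)) / (T99 - T95)` for heat and
  `(logRR(T1) - logRR(T5)) / (T5 - T1)` for cold, exponentiated to RR per
  1 °C (per-degree increase for heat, decrease for cold).
- CIs: Monte Carlo over coefficient draws from `N(coef, vcov)` (default
  1000 draws, seed required); one draw set per city is shared across all EDF
  components and slopes so additivity holds within draws. The MMT is held
  fixed at its point estimate across draws; MMT uncertainty is not
  propagated. RRs at percentiles use delta-method CIs on the log scale.
- Study-level EDF sums attributable and total deaths across cities
  (death-weighted), never an average of city EDFs.

### Clustering

Cities are clustered on their empirical CDF evaluated on a common 0.5 °C
grid spanning the pooled range, with Ward's minimum-variance criterion
(squared-Euclidean merge cost) and the tree cut at `k` clusters (default 12
for real-scale studies; 3 in the synthetic checks). Cities are processed in
lexicographic id order, making assignments input-order invariant. Grouped
models condition on city x year x month x day-of-week strata and place
exposure knots at pooled within-cluster percentiles.

## Synthetic study conditions

The generator emulates the structure of city-level vital-registration data:

- Calendar: 365-day years on real dates with Feb 29 dropped, keeping strata
  sizes regular.
- Temperature: `mean + amplitude * sin(2*pi*doy/365 + phase)` + AR(1) noise.
  Template defaults: mean 21.3 °C and a median city size of ~1,450 deaths/yr
  (~4/day), matching the median city of a large Latin-American multi-city
  sample; amplitude 6 °C, AR(1) 0.7, innovation sd 2 °C give subtropical
  day-to-day variability.
- Mortality: Poisson with multiplicative day-of-week effects, a seasonal
  confounding sinusoid (amplitude 0.05 on the log scale), and a V-shaped
  lagged surface: cumulative RR 1.05 per °C above the true MMT (weights
  geometrically concentrated on lags 0-3) and 1.03 per °C below it (weights
  spread over lags 0-21), zero exactly at the MMT, which is placed at each
  city's 75th temperature percentile. The first 21 days are back-filled with
  the first observed temperature.
- Across cities: mean temperature varies uniformly +-4 °C, amplitude +-20%,
  and baseline rate lognormally with sigma 0.88 — reproducing the ~9.5x
  spread between the 10th and 90th percentile of annual deaths observed in
  such samples. Optional slope heterogeneity adds normal perturbations to the
  per-city log-slopes. Age/cause strata are binomial thinnings with fixed
  shares. All randomness flows from one master seed via `SeedSequence`.

What the generator does **not** emulate: spatial correlation between cities,
influenza epidemics and other co-circulating seasonal mortality shocks,
population trends within the study period, reporting artifacts, or
harvesting/mortality displacement. Passing recovery tests therefore certify
the statistical machinery, not robustness to those features of real data.

## Numerical choices

- Conditional Poisson: Newton with step halving on the exact conditional
  log-likelihood; relative log-likelihood tolerance 1e-9, max 100 iterations;
  non-convergence raises. Zero-total strata are dropped (no conditional
  information) and counted. Columns are mean-centred for conditioning; the
  estimate is invariant to this. A Pearson dispersion statistic is reported,
  and vcov can optionally be scaled by max(1, dispersion) (off by default).
- Known conditioning limit: the 20-column cross-basis information matrix has
  condition number ~1e9, so two mathematically identical covariance matrices
  can differ by ~1e-4 relative after inversion; equivalence tests therefore
  compare information matrices.
- REML: singular within-city covariances are rejected with the city named;
  `Psi` is exactly reproducible given the data (deterministic optimiser
  path).
- Monte Carlo draws factor vcov by symmetric eigendecomposition with
  negative eigenvalues clipped at zero; an indefinite vcov raises.

## Known limitations

- The natural cubic spline cannot represent a first-derivative kink, so when
  the true curve is exactly V-shaped the best-approximating spline (i) shifts
  the curve minimum ~0.5-0.7 °C toward the shallower cold side and (ii)
  overshoots the heat slope measured between P95 and P99 by ~+0.013 on the
  log scale (asymptotically, with the default knots). These are properties of
  the estimand/estimator pair, visible only because the generator's truth is
  piecewise linear; real curves are smooth and do not have this sharp-corner
  mismatch.
- City-level MMT estimates are intrinsically noisy because the curve is
  nearly flat around its minimum; at the default median-city death counts the
  mean absolute MMT error across cities is several °C, shrinking below 1 °C
  only at roughly tenfold larger daily counts.
- EDF confidence intervals ignore MMT uncertainty (fixed per draw), matching
  common practice; coverage at the null is validated empirically in the test
  suite.
- The pooled curve's pooling point and the temperature-range definition are
  conventions recorded in the run manifest, not identified by the data.
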