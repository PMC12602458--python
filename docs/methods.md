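# Methods

## The model

`lagrisk` estimates the short-term association between daily environmental
exposures and daily event counts observed in many small spatial units
(districts), using a two-stage design.

**Stage one (per district).** Daily counts follow a quasi-Poisson model with
log link:

    Y_t ~ quasiPoisson(mu_t),  Var(Y_t) = phi * mu_t
    log mu_t = alpha_s(t) + cb_pollutant(x_t) + cb_temp(T_t) + ns(rh_t) + gamma * holiday_t

`cb` denotes a crossbasis: the effect of an exposure is allowed to be
non-linear in intensity and distributed over lags 0..L, represented by the
tensor product of an exposure basis R (linear, natural cubic spline, or step
function) and a lag basis C evaluated on the integer lag grid. Column (j,k)
at day t is sum_l R_j(x_{t-l}) C_k(l). Relative humidity enters as a
one-dimensional spline of the same-day value or a trailing 3-day running
mean (computed in the panel, not in the basis).

`alpha_s(t)` is a nuisance intercept for the time-stratified case-crossover
stratum of day t: district x year x month x day-of-week. Days within a
stratum serve as each other's controls, absorbing long-term trends,
seasonality and intra-week patterns by design. The stratum intercepts are
profiled out in closed form at every IRLS step (for a log link,
exp(alpha_s) = sum_s y / sum_s exp(x'beta)) and the working least-squares
problem is solved on within-stratum weighted-centered covariates. This is
algebraically identical to including one dummy column per stratum — the test
suite verifies agreement to ~1e-14 — but costs O(n p^2) instead of
O(n (p + S)^2). Strata with zero events are flagged: their intercepts
diverge to -infinity and their fitted means to zero, so they contribute
nothing to the likelihood; their rows and implied parameters are retained in
the n and p used for dispersion so that phi is not artificially inflated.

Dispersion is the Pearson estimate phi = X^2 / (n - p), with p counting the
absorbed stratum intercepts. The covariance of the covariate coefficients is
phi * (X'WX)^-1 on the centered design.

**Summaries.** Every reported quantity is a linear contrast m'beta of the
crossbasis coefficients, so standard errors follow by the delta method:

- lag-specific log RR at increment d above reference r:
  [R(r+d) - R(r)]' B C(l), reported per 10 ug/m3 for PM2.5, PM10, NO2 and
  O3, per 1 for SO2 (its daily levels stay in single digits) and per 100
  for CO (its range spans hundreds);
- cumulative exposure-response at level x: sum over lags of
  [R(x) - R(r)]' B C(l), plotted from zero to the observed maximum;
- reductions: projections of (beta, V) onto the lag dimension (lag-wise
  curve at a stated increment) or the exposure dimension (cumulative
  exposure-response), which reproduce the corresponding full-model
  predictions exactly and are what the second stage pools.

The reference exposure is 0 ug/m3 for all pollutants (configurable). The
95% CI multiplier is the normal quantile 1.959964; an RR is "significant"
when its CI excludes 1.

**Stage two (region).** District reductions y_i with within-district
covariance S_i are pooled under the multivariate random-effects model
y_i ~ N(mu, S_i + Psi). Psi is estimated by REML on a log-Cholesky
parameterisation with L-BFGS-B, started from a moment estimate; if the
optimiser fails, the moment estimate itself is used (sample covariance of
the y_i minus the mean S_i, eigenvalue-clipped to the PSD cone) and the
fallback is logged. The pooled mean is the GLS estimate with weights
(S_i + Psi)^-1. Cochran's Q is computed from the fixed-effect (Psi = 0) fit
and I^2 = max(0, (Q - df)/Q) * 100. With spline exposure bases, knots are
pinned to region-wide quantiles before the district loop so that district
coefficients live in a common basis and are poolable. Districts whose
first-stage fit fails (rank deficiency, non-convergence) are excluded from
pooling and listed in the run's failure manifest. Headline lag-wise RRs come
from pooling the lag-wise reductions (pooling the full coefficient set and
predicting afterwards is also available via the exposure-response path).

## Extensions

**Effect modification.** Subgroup analyses (age <65 vs >=65, male vs female)
fit separate models to subgroup count series; stratified analyses subset
rows by season or districts by urbanicity, then rerun the identical
two-stage code path (the test suite asserts that an all-inclusive pseudo-
stratifier reproduces the main model bit for bit). Season subsets are taken
after stratum assignment; because strata are year x month x weekday and
seasons are whole-month blocks, no stratum straddles seasons. Differences
versus the reference level (>=65, male, urban, winter) are tested per lag
with the two-sample z-test z = (b1 - b2) / sqrt(se1^2 + se2^2).

**Bi-pollutant models.** Confounder mode appends the co-pollutant's own
crossbasis to the design; interaction mode appends products of the primary
crossbasis columns with the co-pollutant's same-day exposure, centered so
the primary block keeps its main-effect interpretation at mean co-exposure.
The co-pollutant modifier basis defaults to linear to keep the dimension
vx*vk rather than vx*vk*vx_co — at district sample sizes a full tensor
interaction is rarely identifiable. PM2.5 with PM10 is refused by default
(Spearman ~0.98; jointly unidentifiable). Single and bi-pollutant fits on
identical rows are compared two ways, both reported: an overall
quasi-likelihood F-test on the added block,
F = (dev_single - dev_bi) / (dp * phi_bi) on (dp, n - p_bi) df, and per-lag
z-contrasts on the lag-wise log-RR difference using the sum of the two
variances. The per-lag form ignores the positive covariance between the two
fits (they share data), which makes it conservative for detecting
differences.

**Sensitivity grid.** Candidate models vary the pollutant transform (linear;
natural splines with 2-4 df), the lag length (3, 7, 10, 14 days), the lag
basis (3-df natural spline; two knots equally spaced on the log-lag scale),
temperature knots (combinations of the 10th/75th/90th percentiles, 14-day
lag as strata or log-spaced spline) and the humidity spline (3-4 df,
same-day or 3-day mean). All candidates are refit on the identical row set
(rows valid at the largest lag anywhere in the grid) and ranked by
Q-AIC = -2 * loglik_Poisson + 2 * p * phi, with phi taken from the largest
converged candidate so the penalty scale is common across the grid
(per-model phi is available as an option). Ties rank the smaller model
first. Non-converging candidates are recorded with their error, never fatal.

`logknots(L, k)` places k knots at exp(log(L) * i/(k+1)), i = 1..k — equal
spacing on the log-lag scale between lag 1 and lag L. The placement rule is
isolated in one function so parity with any external convention is a
one-line change.

## Natural cubic splines

The ns basis is built from the cubic B-spline design on the knot vector with
boundary knots repeated, constrained to zero second derivative at both
boundaries via a null-space projection, and extended linearly beyond the
boundaries using the boundary value and first derivative. Without an
intercept the coefficient space is additionally constrained orthogonal to
the constant function's B-spline coefficients (all ones by partition of
unity), so the returned columns complement the constant in the
natural-spline space. Agreement in span with the classical truncated-power
construction is part of the test suite. When knots are not supplied they sit
at equally spaced quantiles of the data, with boundary knots at the data
range.

## The synthetic generator

The generator emulates the panel structure the analysis assumes, calibrated
to a Northern-Italy 2016-2019 cardiac-arrest setting:

- 96 districts x 1461 days by default; regional mean 25.74 events/day split
  across districts with log-normal baseline heterogeneity (sd 0.30,
  normalised to preserve the regional mean); senior (>=65) share 0.7912 and
  male share 0.5737 by binomial thinning.
- Eight variables (PM2.5, PM10, NO2, O3, SO2, CO, temperature, relative
  humidity). Each is a monotone transform of a standardized latent Gaussian:
  a deterministic seasonal harmonic (winter-peaking for PM/NO2/SO2/CO,
  summer-peaking for O3 and temperature) plus a cross-correlated AR(1)
  process (persistence 0.65) with a regional-shared component (weight 0.70)
  giving spatial coherence. The AR-noise correlation matrix is solved so
  that, combined with the shared seasonality, the final series hit target
  Spearman correlations: 0.98 for PM2.5-PM10, 0.85 for NO2-CO, -0.76 for
  O3-NO2, -0.75 for O3-CO, 0.75 for temperature-O3, -0.58 for
  temperature-CO, -0.50 for temperature-NO2; pairs without a published value
  are fixed once at plausible magnitudes consistent with the sign structure
  (e.g. 0.70 PM2.5-NO2, weak humidity correlations). Infeasible target
  combinations raise an error naming the offending pair.
- Marginals are monotone piecewise-linear quantile transforms anchored at
  the published min/p25/median/p75/max of each variable, so the printed
  quartiles are matched exactly and Spearman structure passes through
  unchanged.
- Counts are Poisson with a per-district-day gamma frailty of shape k
  (variance mu(1 + mu/k), default k = 1, giving mild overdispersion at
  district-level rates around 0.27/day), with day-of-week multipliers
  (normalised to mean 1), an Italian-holiday multiplier (fixed dates plus
  Easter Monday by computus), an optional temperature effect, and the true
  exposure-lag-response surface: per pollutant,
  f(x, l) = scale * g(x) * w_l with g linear, threshold-linear or an
  interpolated curve, plus optional pairwise same-day synergy terms. The
  ground truth is a first-class object, so recovery tests know exactly what
  was planted.

What the generator does **not** emulate: spatial adjacency and advection
(districts are exchangeable), atmospheric chemistry, measurement error in
exposure assignment, long-term pollutant trends, demographic drift, or
harvesting dynamics. Passing recovery tests therefore demonstrate that the
estimator chain is unbiased and calibrated under the assumed data-generating
structure — not that those field complications are handled.

## Numerical choices

- IRLS converges on relative coefficient change < 1e-9, at most 100
  iterations; non-convergence is reported, never silent. Rank deficiency
  after stratum absorption raises an error naming the collinear columns.
- REML uses ftol 1e-12 / gtol 1e-9; the moment start makes convergence
  routine at the dimensions used here (<= 8).
- Q-AIC comparisons across different row sets raise.
- The first L rows of each district series (incomplete lag history) are
  dropped, not imputed; rows with missing values are dropped consistently
  from response, design and strata.
- Pipeline outputs are written with a fixed 12-significant-digit float
  format; identical seed and configuration reproduce outputs byte for byte.

## Replicated studies and problem sizes

The `experiments` module runs the operating-characteristic studies used by
the tests and the acceptance script, at sizes chosen to give stable rates at
interactive runtimes: recovery coverage with 40 replicates of 20 districts x
4 years (truth: linear PM2.5 effect 0.0029 log-RR per ug/m3 over lags 0-1);
null calibration with 40 replicates of 10 districts across all six
pollutants; z-test uniformity on 500 independent pairs of null single-
district fits (independence across tests keeps the Kolmogorov-Smirnov check
valid — lag-wise p-values within one fit are correlated through the smooth
lag basis and would not be an honest KS sample); and Q-AIC lag selection
with 50 replicates of an unconstrained 3-lag vs 14-lag candidate pair, where
the longer model spends one parameter per extra lag and the dimension
penalty is the deciding term.

## Known limitations

- The conditional model retains quasi-Poisson dispersion rather than a
  conditional-logistic likelihood; for individually matched designs use a
  dedicated tool.
- Per-lag bi-pollutant heterogeneity tests ignore the covariance between
  nested fits (conservative).
- BLUP back-prediction of district-specific curves and meta-regression on
  district covariates are documented extensions, not implemented.
- The bundled holiday calendar is the Italian national list; other calendars
  are supplied via a one-date-per-line file.
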