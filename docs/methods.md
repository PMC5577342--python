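# Methods

This note records the models implemented in `rhinocast`, the assumptions
behind them, the synthetic data they are exercised on, and the numerical and
design choices that were genuinely open.

## The analysis pipeline

**Windows.** All quantities live on consecutive, non-overlapping, half-open
windows `[start + i*L, start + (i+1)*L)` with `L = 14` days. The study-shaped
calendar (`study_window_spec()`) is 92 fortnights anchored at 2007-02-04.
The anchor and the window count are explicit configuration: a ~4-year span
contains more than 92 fortnights, so the original sampling calendar is not
derivable from the span alone and alignment to the first visit date versus
calendar fortnights is a user decision. The "incidence" date of a record is
its visit date (the dated event available in a registry extract); the date
column is configurable.

**Temporal trend.** Biweekly counts are modelled as sparse-lag
autoregressions `x_t = Σ_k φ_k x_{t−k} + ε_t` with no intercept. Because the
equations carry no intercept, `fit_ar` removes the sample mean first and
stores it on the model (`series_mean`), adding it back for trend prediction;
a `demean=False` escape hatch exists for signals known to be centred, where
a zero-noise recursion is then recovered exactly. Estimation is conditional
least squares — OLS of `x_t` on its chosen lags — which is deterministic,
needs no numerical optimiser, and is asymptotically equivalent to maximum
likelihood for pure AR models (all the final trend models are pure AR).
Stationarity is checked via the roots of `1 − Σ φ_k z^k`; all three
published coefficient sets are comfortably stationary (smallest root
modulus 1.20).

Supporting conventions, chosen for internal consistency:

* ACF uses the biased (divide-by-n) estimator, which keeps the sample
  autocovariance sequence positive semi-definite.
* PACF is the Durbin–Levinson recursion on that ACF (identical to
  statsmodels' `method="ldb"`; the test suite cross-checks this).
* The Ljung–Box statistic `Q = n(n+2) Σ_{k≤m} r_k²/(n−k)` is referred to
  χ²(m − p) when testing residuals of a p-coefficient AR fit.
* The BIC grid over ARMA(p, q), `BIC = n ln σ̂² + (p+q) ln n`, scores
  q > 0 cells by a Hannan–Rissanen two-stage regression (innovations
  proxied by long-AR residuals) so no iterative likelihood optimisation is
  needed; all cells are conditioned on a common sample so their BICs are
  comparable, and ties break toward smaller p+q, then smaller p. In
  simulation the grid picks (1,0) for an AR(1) with φ = 0.8 (n = 2000) in
  ≈99/100 seeds and (0,0) for white noise in ≈100/100.

**Composite index.** `CMP = E·TD/P` with E in hPa, TD in °C, P in hPa. The
units are deliberately not configurable: on this convention the index spans
roughly −0.1..0.8 over a Beijing-like year, which is the scale the published
quadratic coefficients presume (e.g. `404.45 x²` peaking for x < 1); Kelvin
would move the index to ~70–90 and invalidate them. Negative values
(sub-zero fortnight-mean minimum temperature) are legitimate winter states
and pass through — the quadratics are defined on all reals.

**Quadratic models and evaluation.** `fit_quadratic` is OLS on the design
`[x², x, 1]`, with `R² = 1 − SSE/SST` and the conventional overall F with
(2, n−3) degrees of freedom (the source material reports an F value without
stating df; this is the standard choice for a two-regressor linear model).
Degenerate cases: zero explainable signal gives F = 0 (p = 1), a perfect fit
with signal gives F = ∞ (p = 0), and a rank-deficient design (constant x, or
two distinct x values) raises rather than returning garbage. Model
comparison uses a single uniform random train/test split shared across all
(group, predictor) cells, scoring each cell by RMSE on the held-out windows
only. Real-valued predictions are rounded half-up before severity
classification (the level definitions are on integer counts; half-up is the
obvious convention and is applied uniformly).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any particular station record:

* **Meteorology.** Daily minimum temperature = annual mean 8 °C + sinusoid
  of amplitude 14 °C (period 365.25 d, peaking at day-of-year ≈200,
  northern-hemisphere mid-July) + AR(1) anomaly noise (marginal sd 3 °C,
  persistence φ = 0.8, i.e. synoptic-scale weather spells). Vapour pressure
  shares the phase (13 ± 11 hPa, noise sd 3 hPa, truncated > 0); sea-level
  pressure is in anti-phase (1016 ∓ 9 hPa, noise sd 5 hPa) — the
  monsoon-continental regime of the North China Plain. Companion variables
  (tmax/tavg via fixed diurnal offsets, relative humidity, wet-day
  precipitation, wind, dew point from vapour pressure by inverted Magnus
  formula) make the CSV realistic but carry no signal the pipeline uses.
* **Incidence.** Per window, the CMP is computed from the simulated window
  means and pushed through the published quadratic link for the group;
  group defaults are the published coefficient sets. A mild AR(1)
  perturbation on the window mean (persistence 0.5; innovation sd 3/1/0.5
  counts for pollen/dust-mite/mould, i.e. small relative to the Poisson
  noise) mimics the serial dependence the trend models describe. The mean is
  floored at `mu_floor = 0.5` so the count distribution stays valid if the
  parabola dips below zero, and the count is drawn Poisson (default) or
  negative-binomial (gamma–Poisson, variance μ + μ²/k) for overdispersed
  settings; a zero-variance "deterministic" hook rounds the mean, for exact
  tests. Counts are expanded to visit records dated uniformly within the
  window — the analysis uses window totals only, so intra-window placement
  is immaterial.

Under these defaults the simulated mould row of the RMSE grid reproduces
the characteristic margins of the real analysis (CMP ≈ 2.56 vs tmin ≈ 2.61
averaged over seeds), and simulated pollen totals (~3500 over 92 windows)
are of the order of the real pollen cohort.

**What the generator does not emulate:** pollen-count series, air-pollution
covariates, demographic structure, reporting artefacts (holidays, clinic
closures), or any spatial variation. Passing tests therefore demonstrate
that the pipeline's statistics behave as designed on data satisfying its
assumptions — not that the published coefficient values are correct for any
real cohort.

## Problem sizes and power

Statistical checks use sizes chosen for resolving power at desk scale:

* Trend-coefficient recovery simulates 100,000 points (sampling sd of a
  lag-1 estimate ≈0.002, comfortably inside the ±0.01 assertion).
* The Ljung–Box type-I calibration uses 1000 replicates of n = 1000.
* The predictor-ranking property (CMP attains the row-minimum held-out RMSE
  for the pollen and mould groups in the majority of 100 seeded runs) is
  evaluated on a 552-fortnight simulated record with a 72.8% train share.
  At 92 windows the mould margin (~2% of RMSE) is far below what a single
  25-window validation set can resolve — the per-seed "winner" is close to
  a coin flip there, for the real analysis as much as for the simulation —
  while at 552 windows the ranking is stable (CMP wins ≈100/100 pollen,
  ≈78/100 mould). The 92-window configuration remains the default
  everywhere else.
* The end-to-end link-recovery check (generate → aggregate → CMP → refit)
  uses a cold-climate generator configuration (annual-mean minimum
  temperature 0 °C) so the index spans both signs: with CMP confined to a
  narrow positive range, `x` and `x²` are nearly collinear and the linear
  coefficient is identifiable only to ~±20% at 500 windows. With the
  sign-spanning design and 1000 windows, all three pollen-link coefficients
  are recovered within 10% in 96/100 replicates. This collinearity is a
  genuine limitation of quadratic-in-CMP fits on warm-climate records and
  is worth knowing about before interpreting fitted coefficients.

## Reproducibility

Every stochastic stage takes a seed; the pipeline derives per-stage seeds
from one global seed by hashing the stage name, so stages can be re-run in
isolation and two runs with the same configuration and seed are
byte-identical. Artifacts are stamped with a hash of the scientific
configuration (output paths and log level excluded).

## Known limitations

* Conditional least squares conditions on the first max-lag observations;
  for the 92-window series this costs a few samples relative to exact ML —
  immaterial at the accuracy the trend models claim, but a difference in
  principle.
* The BIC grid's q > 0 cells are scored by a regression approximation
  (Hannan–Rissanen), adequate for order *selection*; fitted MA coefficients
  are never reported.
* OLS on counts ignores heteroscedasticity (Poisson variance grows with the
  mean); a count-GLM alternative is deliberately out of scope because the
  implemented analysis is ordinary least squares on counts.
* The severity classification applies the published fixed cut-offs
  (16/52/104); they are not re-derived from any distribution.
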