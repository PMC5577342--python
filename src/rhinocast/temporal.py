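"""Autoregressive temporal-trend modelling of biweekly incidence.

Workflow: inspect ACF/PACF, choose an order on a BIC grid, fit a
(possibly sparse-lag) autoregression by conditional least squares, and
check the residuals with a Ljung-Box white-noise test.

Conventions
-----------
* The sample ACF uses the biased (divide-by-n) estimator, which keeps
  the autocovariance sequence positive semi-definite.
* The PACF is obtained from the sample ACF by the Durbin-Levinson
  recursion, so ``pacf[1] == acf[1]`` exactly.
* AR fits have no intercept: the series is demeaned first and the mean
  is stored on the model, to be added back when predicting the trend.
* Estimation is conditional least squares (OLS of x_t on its chosen
  lags), which is exact enough for pure-AR trend models and fully
  deterministic.
* The BIC grid scores ARMA(p, q) cells via a Hannan-Rissanen two-stage
  regression (innovations proxied by long-AR residuals) so that q > 0 is
  covered without iterative likelihood optimisation; final trend models
  are pure AR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (DegenerateSeriesError, EstimationError,
                     InvalidParameterError)

__all__ = [
    "ARModel",
    "WhiteNoiseResult",
    "acf",
    "pacf",
    "select_order",
    "fit_ar",
    "white_noise_test",
    "simulate_ar",
]


# ---------------------------------------------------------------------------
# model containers

@dataclass(frozen=True)
class ARModel:
    """Sparse-lag autoregression x_t = sum_k phi_k * x_{t-k} + eps_t.

    ``lags`` is an ordered tuple of positive lags; ``coefficients`` holds
    one phi per lag.  The model is fitted on (and simulates around)
    ``series_mean``; ``innovation_sd`` is the residual standard
    deviation of eps_t in count units.
    """

    lags: tuple[int, ...]
    coefficients: tuple[float, ...]
    series_mean: float = 0.0
    innovation_sd: float = 1.0
    group: str | None = None

    def __post_init__(self) -> None:
        if len(self.lags) != len(self.coefficients):
            raise InvalidParameterError(
                f"{len(self.lags)} lags but {len(self.coefficients)} coefficients")
        if any(int(k) != k or k < 1 for k in self.lags):
            raise InvalidParameterError(f"lags must be positive integers: {self.lags}")
        if len(set(self.lags)) != len(self.lags):
            raise InvalidParameterError(f"duplicate lags: {self.lags}")
        if self.innovation_sd < 0:
            raise InvalidParameterError("innovation_sd must be >= 0")

    @property
    def max_lag(self) -> int:
        return max(self.lags) if self.lags else 0

    @property
    def is_stationary(self) -> bool:
        """True iff all roots of 1 - sum phi_k z^k lie outside the unit circle."""
        if not self.lags:
            return True
        poly = np.zeros(self.max_lag + 1)
        poly[0] = 1.0
        for k, phi in zip(self.lags, self.coefficients):
            poly[k] = -phi
        roots = np.roots(poly[::-1])
        return bool(np.all(np.abs(roots) > 1.0))

    def to_dict(self) -> dict:
        return {
            "lags": list(self.lags),
            "coefficients": list(self.coefficients),
            "series_mean": self.series_mean,
            "innovation_sd": self.innovation_sd,
            "group": self.group,
            "stationary": self.is_stationary,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ARModel":
        return cls(lags=tuple(int(k) for k in d["lags"]),
                   coefficients=tuple(float(c) for c in d["coefficients"]),
                   series_mean=float(d.get("series_mean", 0.0)),
                   innovation_sd=float(d.get("innovation_sd", 1.0)),
                   group=d.get("group"))


@dataclass(frozen=True)
class WhiteNoiseResult:
    """Ljung-Box portmanteau test outcome on model residuals."""

    statistic: float
    dof: int
    p_value: float


# ---------------------------------------------------------------------------
# correlograms

def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise DegenerateSeriesError("series contains non-finite values")
    return arr


def acf(series, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag.

    ``acf(x, m)[0]`` is exactly 1; every value lies in [-1, 1].  The
    divide-by-n convention is used for the autocovariances.
    """
    x = _as_series(series)
    n = x.size
    if max_lag < 0:
        raise InvalidParameterError("max_lag must be >= 0")
    if n <= max_lag + 1:
        raise InvalidParameterError(
            f"series length {n} must exceed max_lag + 1 = {max_lag + 1}")
    d = x - x.mean()
    c0 = float(d @ d) / n
    if c0 == 0.0:
        raise DegenerateSeriesError("constant series has no autocorrelation")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = float(d[k:] @ d[:-k]) / n / c0
    return out


def pacf(series, max_lag: int) -> np.ndarray:
    """Sample partial autocorrelation at lags 0..max_lag (lag 0 set to 1).

    Computed by the Durbin-Levinson recursion on the biased sample ACF;
    the lag-1 value equals the lag-1 ACF by construction.
    """
    if max_lag < 1:
        raise InvalidParameterError("max_lag must be >= 1")
    rho = acf(series, max_lag)
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    phi_prev = np.empty(0)
    for m in range(1, max_lag + 1):
        if m == 1:
            num = rho[1]
            den = 1.0
        else:
            num = rho[m] - phi_prev @ rho[m - 1:0:-1]
            den = 1.0 - phi_prev @ rho[1:m]
        if den <= 0:
            raise DegenerateSeriesError(
                f"Durbin-Levinson breakdown at lag {m} (non-PD autocorrelation)")
        phi_mm = num / den
        out[m] = phi_mm
        phi = np.empty(m)
        phi[:m - 1] = phi_prev - phi_mm * phi_prev[::-1]
        phi[m - 1] = phi_mm
        phi_prev = phi
    return out


# ---------------------------------------------------------------------------
# fitting

def fit_ar(series, lags: Sequence[int], *, group: str | None = None,
           demean: bool = True) -> ARModel:
    """Conditional-least-squares fit of a sparse-lag autoregression.

    The series is demeaned (the trend equations carry no intercept);
    coefficients come from an OLS regression of x_t on
    {x_{t-k} : k in lags} with no intercept; the mean is stored on the
    returned model and added back for trend prediction.  Supports
    arbitrary sparse lag sets such as {1, 4}.  ``demean=False`` fits the
    raw series, appropriate for signals known to be centred (or exact
    zero-noise recursions, which have no stationary mean to remove).
    """
    lag_t = tuple(sorted(int(k) for k in lags))
    if not lag_t or any(k < 1 for k in lag_t) or len(set(lag_t)) != len(lag_t):
        raise InvalidParameterError(f"lags must be distinct positive integers: {lags}")
    x = _as_series(series)
    n = x.size
    m = lag_t[-1]
    if n <= m + len(lag_t) + 2:
        raise InvalidParameterError(
            f"series length {n} too short for lags {lag_t}")
    mean = float(x.mean()) if demean else 0.0
    d = x - mean
    if np.allclose(d, 0.0):
        raise EstimationError("constant series: singular design")
    y = d[m:]
    X = np.column_stack([d[m - k:n - k] for k in lag_t])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError(
            f"singular design for lags {lag_t} (rank {rank} < {X.shape[1]})")
    resid = y - X @ coef
    dof = max(y.size - len(lag_t), 1)
    sd = float(np.sqrt(resid @ resid / dof))
    return ARModel(lags=lag_t, coefficients=tuple(float(c) for c in coef),
                   series_mean=mean, innovation_sd=sd, group=group)


def _hr_cell_rss(d: np.ndarray, e: np.ndarray, p: int, q: int,
                 start: int) -> tuple[float, int]:
    """RSS and sample size of one ARMA(p,q) Hannan-Rissanen regression.

    ``d`` is the demeaned series, ``e`` the long-AR residual proxy for
    the innovations (aligned with ``d``, NaN where undefined), ``start``
    the common first usable index so all grid cells share the sample.
    """
    n = d.size
    y = d[start:]
    cols = [d[start - k:n - k] for k in range(1, p + 1)]
    cols += [e[start - k:n - k] for k in range(1, q + 1)]
    if cols:
        X = np.column_stack(cols)
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise EstimationError(f"singular design at (p={p}, q={q})")
        resid = y - X @ coef
    else:
        resid = y
    return float(resid @ resid), y.size


def select_order(series, max_p: int, max_q: int) -> tuple[int, int]:
    """Pick (p, q) minimising BIC on an exhaustive (max_p+1)x(max_q+1) grid.

    BIC = n*ln(residual variance) + k*ln(n) with k = p + q, all cells
    scored on a common conditioning sample so values are comparable.
    Ties break toward smaller p + q, then smaller p.
    """
    if max_p < 0 or max_q < 0:
        raise InvalidParameterError("max_p and max_q must be >= 0")
    x = _as_series(series)
    n = x.size
    if n < 10 * (max_p + max_q + 1):
        raise InvalidParameterError(
            f"series length {n} < 10*(max_p+max_q+1) = {10 * (max_p + max_q + 1)}")
    if max_p == 0 and max_q == 0:
        return (0, 0)
    d = x - x.mean()
    if np.allclose(d, 0.0):
        raise DegenerateSeriesError("constant series")

    # innovation proxy: residuals of a long autoregression
    h = min(max(2 * max(max_p, max_q), 4) + max_p, n // 4)
    e = np.full(n, np.nan)
    if max_q > 0:
        long_model = fit_ar(d, range(1, h + 1))
        Xl = np.column_stack([d[h - k:n - k] for k in range(1, h + 1)])
        e[h:] = d[h:] - Xl @ np.asarray(long_model.coefficients)
    start = (h if max_q > 0 else 0) + max(max_p, max_q)

    results: list[tuple[float, int, int, int]] = []
    failures: dict[tuple[int, int], str] = {}
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            try:
                rss, n_eff = _hr_cell_rss(d, e, p, q, start)
                if rss <= 0:
                    rss = np.finfo(float).tiny
                bic = n_eff * np.log(rss / n_eff) + (p + q) * np.log(n_eff)
                results.append((bic, p + q, p, q))
            except EstimationError as err:  # pragma: no cover - rare
                failures[(p, q)] = str(err)
    if not results:
        raise EstimationError(f"all grid cells failed: {failures}")
    results.sort(key=lambda t: (t[0], t[1], t[2]))
    _, _, p, q = results[0]
    return (p, q)


# ---------------------------------------------------------------------------
# diagnostics and simulation

def white_noise_test(residuals, n_lags: int, *, model_df: int = 0) -> WhiteNoiseResult:
    """Ljung-Box portmanteau test that residuals are white noise.

    Q = n(n+2) * sum_{k=1}^{m} r_k^2 / (n-k), referred to a chi-square
    with m - model_df degrees of freedom (``model_df`` = number of fitted
    AR coefficients, when testing model residuals).
    """
    r = _as_series(residuals)
    n = r.size
    if n_lags < 1:
        raise InvalidParameterError("n_lags must be >= 1")
    if n <= n_lags + 1:
        raise InvalidParameterError(
            f"need more residuals ({n}) than n_lags + 1 ({n_lags + 1})")
    if model_df < 0 or model_df >= n_lags:
        raise InvalidParameterError(
            f"model_df must lie in [0, n_lags), got {model_df}")
    rho = acf(r, n_lags)  # raises DegenerateSeriesError on constant input
    ks = np.arange(1, n_lags + 1)
    q = float(n * (n + 2) * np.sum(rho[1:] ** 2 / (n - ks)))
    dof = n_lags - model_df
    p = float(stats.chi2.sf(q, dof))
    return WhiteNoiseResult(statistic=q, dof=dof, p_value=p)


def simulate_ar(model: ARModel, n: int, burn_in: int | None = None,
                seed: int | np.random.SeedSequence | None = None) -> np.ndarray:
    """Simulate ``n`` points from an AR model with Gaussian innovations.

    The first ``burn_in`` samples (default and minimum ``10 * max_lag``)
    are discarded so the output is effectively a draw from the stationary
    distribution, shifted by ``model.series_mean``.  Seed-deterministic.
    """
    if not model.is_stationary:
        raise InvalidParameterError(
            f"model with lags {model.lags} and coefficients "
            f"{model.coefficients} is not stationary")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    min_burn = 10 * model.max_lag
    if burn_in is None:
        burn_in = min_burn
    if burn_in < min_burn:
        raise InvalidParameterError(
            f"burn_in must be >= 10*max(lags) = {min_burn}, got {burn_in}")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    eps = rng.normal(0.0, model.innovation_sd, size=total)
    if not model.lags:
        return model.series_mean + eps[burn_in:]
    m = model.max_lag
    x = np.zeros(total + m)
    phi = np.asarray(model.coefficients)
    lag_arr = np.asarray(model.lags)
    for t in range(total):
        x[t + m] = phi @ x[t + m - lag_arr] + eps[t]
    return model.series_mean + x[m + burn_in:]
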