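"""Synthetic daily meteorology and AR visit records.

The original outpatient records are not redistributable, so every
downstream stage is exercised on simulated data carrying the same
statistical structure the analysis assumes:

* Daily minimum temperature follows a sinusoid with period 365.25 d
  peaking near mid-July (day-of-year ~200, northern hemisphere) plus
  AR(1) weather noise.  Vapour pressure shares the phase (humid
  summers); sea-level pressure is in anti-phase (winter highs), the
  Beijing-like regime.
* Biweekly AR counts are generated through the quadratic
  composite-index link: per window the CMP is computed from the window
  means, pushed through y = a*x^2 + b*x + c (floored at a small positive
  mean), optionally perturbed by an autoregressive residual, and a count
  is drawn from a Poisson or negative-binomial noise model.  Counts are
  expanded into dated visit records placed uniformly within the window
  (the analysis only uses window totals, so intra-window placement is
  immaterial).

Defaults emulate ~4 years of the Beijing annual cycle with the published
link coefficients, producing the characteristic Aug-Sep incidence peak.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .composite import cmp_series
from .errors import InvalidParameterError
from .preprocess import WindowSpec, average_meteorology
from .quadratic import reference_models

__all__ = [
    "MeteoSimParams",
    "IncidenceSimParams",
    "generate_meteorology",
    "generate_incidence",
    "default_incidence_params",
]

METEO_COLUMNS = ["date", "tmax_c", "tavg_c", "tmin_c", "rh_pct", "vapour_hpa",
                 "precip_mm", "wind_ms", "slp_hpa", "dewpoint_c"]

#: Day-of-year at which the seasonal sinusoid peaks (mid-July).
SEASONAL_PEAK_DOY = 200.0
TROPICAL_YEAR_DAYS = 365.25


@dataclass(frozen=True)
class MeteoSimParams:
    """Beijing-like daily meteorology simulation parameters.

    Annual means/amplitudes are in the variable's own units (degC for
    temperature, hPa for vapour and sea-level pressure); ``noise_sd``
    maps variable name ("tmin", "vapour", "slp") to the daily noise
    standard deviation, and ``ar_coeff_noise`` gives the shared AR(1)
    persistence of that weather noise.
    """

    n_days: int = 1461
    start_date: dt.date = dt.date(2007, 2, 4)
    tmin_annual_mean: float = 8.0
    tmin_annual_amplitude: float = 14.0
    vapour_mean: float = 13.0
    vapour_amplitude: float = 11.0
    slp_mean: float = 1016.0
    slp_amplitude: float = 9.0
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"tmin": 3.0, "vapour": 3.0, "slp": 5.0})
    ar_coeff_noise: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 28:
            raise InvalidParameterError(
                f"n_days must be >= 28 (two biweekly windows), got {self.n_days}")
        for name, amp in (("tmin", self.tmin_annual_amplitude),
                          ("vapour", self.vapour_amplitude),
                          ("slp", self.slp_amplitude)):
            if amp < 0:
                raise InvalidParameterError(f"{name} amplitude must be >= 0")
        if not abs(self.ar_coeff_noise) < 1:
            raise InvalidParameterError(
                f"|ar_coeff_noise| must be < 1, got {self.ar_coeff_noise}")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise InvalidParameterError(f"noise_sd[{name!r}] must be >= 0")


@dataclass(frozen=True)
class IncidenceSimParams:
    """Count-generating parameters for one allergen group.

    ``link_coefficients`` are (a, b, c) of the quadratic composite-index
    link; ``noise_model`` is "poisson", "negative_binomial" (with
    ``dispersion`` k, variance mu + mu^2/k) or "deterministic" (half-up
    rounding of the mean — a test hook with zero count noise).
    ``residual_ar_coeffs`` optionally adds a stationary autoregressive
    perturbation (innovation sd ``residual_sd``, count units) to the
    window means before drawing counts.
    """

    group: str = "pollen"
    link_coefficients: tuple[float, float, float] = (404.45, -51.32, 16.88)
    noise_model: str = "poisson"
    dispersion: float = 10.0
    residual_ar_coeffs: Mapping[int, float] = field(default_factory=dict)
    residual_sd: float = 0.0
    mu_floor: float | None = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("poisson", "negative_binomial", "deterministic"):
            raise InvalidParameterError(
                f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "negative_binomial" and self.dispersion <= 0:
            raise InvalidParameterError("dispersion must be > 0")
        if self.mu_floor is not None and self.mu_floor < 0:
            raise InvalidParameterError("mu_floor must be >= 0 (or None)")
        if self.residual_sd < 0:
            raise InvalidParameterError("residual_sd must be >= 0")
        for k, phi in self.residual_ar_coeffs.items():
            if int(k) != k or k < 1:
                raise InvalidParameterError(f"residual lag must be >= 1: {k}")


def default_incidence_params(seed: int = 0) -> dict[str, IncidenceSimParams]:
    """Study-conditioned generator settings for the three allergen groups.

    Link coefficients are the published quadratic models; each group gets
    Poisson count noise plus a mild AR(1) residual on the window mean
    (persistence 0.5, innovation sd scaled to the group's count level) to
    mimic the serial dependence the trend models describe.
    """
    sds = {"pollen": 3.0, "dust_mite": 1.0, "mould": 0.5}
    return {
        g: IncidenceSimParams(
            group=g,
            link_coefficients=(m.a, m.b, m.c),
            noise_model="poisson",
            residual_ar_coeffs={1: 0.5},
            residual_sd=sds[g],
            seed=seed + i,
        )
        for i, (g, m) in enumerate(reference_models().items())
    }


def _seasonal(day_index: np.ndarray, start: dt.date) -> np.ndarray:
    """Unit-amplitude seasonal cycle, +1 at day-of-year ~200."""
    doy0 = start.timetuple().tm_yday - 1
    phase = 2.0 * np.pi * (doy0 + day_index - (SEASONAL_PEAK_DOY - 1)) / TROPICAL_YEAR_DAYS
    return np.cos(phase)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    e = rng.normal(0.0, innov_sd, size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + e[t]
    return out


def _dewpoint_from_vapour(e_hpa: np.ndarray) -> np.ndarray:
    # Magnus formula inverted: e = 6.112 * exp(17.67 Td / (Td + 243.5))
    ln_ratio = np.log(np.maximum(e_hpa, 1e-3) / 6.112)
    return 243.5 * ln_ratio / (17.67 - ln_ratio)


def generate_meteorology(params: MeteoSimParams) -> pd.DataFrame:
    """Simulate one daily meteorology table.

    Returns a DataFrame with the standard columns (``date, tmax_c,
    tavg_c, tmin_c, rh_pct, vapour_hpa, precip_mm, wind_ms, slp_hpa,
    dewpoint_c``), one row per day, no missing values.  Identical
    parameters and seed give identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_days
    days = np.arange(n)
    s = _seasonal(days, params.start_date)
    phi = params.ar_coeff_noise

    tmin = (params.tmin_annual_mean + params.tmin_annual_amplitude * s
            + _ar1_noise(rng, n, params.noise_sd.get("tmin", 0.0), phi))
    vapour = (params.vapour_mean + params.vapour_amplitude * s
              + _ar1_noise(rng, n, params.noise_sd.get("vapour", 0.0), phi))
    vapour = np.maximum(vapour, 0.1)  # physical truncation
    slp = (params.slp_mean - params.slp_amplitude * s
           + _ar1_noise(rng, n, params.noise_sd.get("slp", 0.0), phi))
    slp = np.maximum(slp, 1.0)

    # companion variables: diurnal offsets and humidity-coupled fields
    tavg = tmin + 6.0
    tmax = tmin + 11.0
    rh = np.clip(55.0 + 15.0 * s + _ar1_noise(rng, n, 8.0, phi), 5.0, 100.0)
    wet = rng.random(n) < np.clip(0.12 + 0.18 * s, 0.02, 0.5)
    precip = np.where(wet, rng.exponential(6.0, size=n), 0.0)
    wind = 2.3 + np.abs(_ar1_noise(rng, n, 1.0, phi))
    dewpoint = _dewpoint_from_vapour(vapour)

    dates = pd.date_range(params.start_date, periods=n, freq="D")
    return pd.DataFrame({
        "date": dates.date, "tmax_c": tmax, "tavg_c": tavg, "tmin_c": tmin,
        "rh_pct": rh, "vapour_hpa": vapour, "precip_mm": precip,
        "wind_ms": wind, "slp_hpa": slp, "dewpoint_c": dewpoint,
    })


def window_means_and_cmp(meteo: pd.DataFrame, window_spec: WindowSpec) -> pd.DataFrame:
    """Window-mean meteorology with the composite index appended."""
    means = average_meteorology(meteo, window_spec)
    means["cmp"] = cmp_series(means)
    return means


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 params: IncidenceSimParams) -> np.ndarray:
    if params.noise_model == "deterministic":
        return np.floor(mu + 0.5).astype(int)
    if params.noise_model == "poisson":
        return rng.poisson(mu).astype(int)
    # negative binomial via gamma-Poisson mixture: var = mu + mu^2/k
    k = params.dispersion
    lam = rng.gamma(shape=k, scale=mu / k)
    return rng.poisson(lam).astype(int)


def generate_incidence(
    meteo: pd.DataFrame,
    params: IncidenceSimParams,
    window_spec: WindowSpec,
) -> pd.DataFrame:
    """Simulate dated visit records for one allergen group.

    For each window the composite index x is computed from the window
    means, the mean incidence is mu = max(a*x^2 + b*x + c (+ AR residual),
    mu_floor), and a count is drawn from the configured noise model; the
    count is expanded into that many records dated uniformly at random
    within the window.  Returns a DataFrame with columns ``date, group``.
    """
    rng = np.random.default_rng(params.seed)
    means = window_means_and_cmp(meteo, window_spec)
    a, b, c = params.link_coefficients
    x = means["cmp"].to_numpy()
    mu = a * x ** 2 + b * x + c

    if params.residual_sd > 0 and params.residual_ar_coeffs:
        from .temporal import ARModel, simulate_ar
        res_model = ARModel(
            lags=tuple(sorted(params.residual_ar_coeffs)),
            coefficients=tuple(params.residual_ar_coeffs[k]
                               for k in sorted(params.residual_ar_coeffs)),
            series_mean=0.0, innovation_sd=params.residual_sd)
        mu = mu + simulate_ar(res_model, len(mu),
                              seed=np.random.SeedSequence(params.seed).spawn(1)[0])
    elif params.residual_sd > 0:
        mu = mu + rng.normal(0.0, params.residual_sd, size=len(mu))

    if params.mu_floor is None:
        if np.any(mu < 0):
            i = int(np.argmin(mu))
            raise InvalidParameterError(
                f"window {i}: quadratic link gives negative mean incidence "
                f"({mu[i]:.3f}); set mu_floor to a non-negative value")
    else:
        mu = np.maximum(mu, params.mu_floor)

    counts = _draw_counts(rng, mu, params)
    records: list[dict] = []
    for i, cnt in enumerate(counts):
        if cnt <= 0:
            continue
        offsets = rng.integers(0, window_spec.window_length, size=cnt)
        start = window_spec.window_start(i)
        for o in np.sort(offsets):
            records.append({"date": start + dt.timedelta(days=int(o)),
                            "group": params.group})
    return pd.DataFrame(records, columns=["date", "group"])


def generate_study_dataset(
    seed: int = 0,
    *,
    meteo_params: MeteoSimParams | None = None,
    window_spec: WindowSpec | None = None,
    incidence_params: Mapping[str, IncidenceSimParams] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: one 4-year meteorology table plus visit
    records for all three allergen groups under the default study
    conditions.  Returns ``(meteo, visits)``.
    """
    from .preprocess import study_window_spec
    if window_spec is None:
        window_spec = study_window_spec()
    if meteo_params is None:
        meteo_params = MeteoSimParams(seed=seed)
    if incidence_params is None:
        incidence_params = default_incidence_params(seed=seed + 1)
    meteo = generate_meteorology(meteo_params)
    visits = pd.concat(
        [generate_incidence(meteo, p, window_spec)
         for p in incidence_params.values()],
        ignore_index=True)
    return meteo, visits
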