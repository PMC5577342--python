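"""Quadratic incidence models y = a*x^2 + b*x + c.

Biweekly AR case counts are regressed on a single meteorological
predictor (window-mean minimum temperature, sea-level pressure or vapour
pressure) or on the composite index CMP.  Fits are ordinary least
squares on the design [x^2, x, 1]; the overall regression F statistic
uses the conventional (2, n-3) degrees of freedom.

``reference_models()`` returns the published CMP-based incidence models
for the three allergen groups, usable as fixed forecasting equations
without refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import DomainError, EstimationError, InvalidParameterError

__all__ = [
    "QuadraticModel",
    "fit_quadratic",
    "predict_incidence",
    "reference_models",
    "REFERENCE_COHORT",
]

#: Cohort composition of the underlying four-year outpatient study:
#: total distinct AR patients and the size of each allergen group.
REFERENCE_COHORT = {
    "total": 10914,
    "pollen": 3547,
    "dust_mite": 4976,
    "mould": 2391,
}


@dataclass(frozen=True)
class QuadraticModel:
    """One fitted (or published) quadratic incidence model.

    ``a, b, c`` are in counts per predictor-unit^2, counts per
    predictor-unit, and counts.  Fit statistics are ``None`` on
    published models, which carry coefficients only.
    """

    a: float
    b: float
    c: float
    predictor_name: str
    group: str | None = None
    r_squared: float | None = None
    f_value: float | None = None
    p_value: float | None = None
    n_fit: int | None = None

    def __post_init__(self) -> None:
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidParameterError(f"r_squared out of [0,1]: {self.r_squared}")
        if self.f_value is not None and self.f_value < 0:
            raise InvalidParameterError(f"f_value must be >= 0: {self.f_value}")
        if self.n_fit is not None and self.n_fit < 4:
            raise InvalidParameterError("n_fit must be >= 4 for F(2, n-3)")

    def predict(self, x):
        return predict_incidence(self, x)

    @property
    def vertex(self) -> float:
        """Predictor value -b/(2a) at the parabola's extremum."""
        if self.a == 0:
            raise DomainError("degenerate (linear) model has no vertex")
        return -self.b / (2.0 * self.a)

    def to_dict(self) -> dict:
        return {"group": self.group, "predictor": self.predictor_name,
                "a": self.a, "b": self.b, "c": self.c,
                "r_squared": self.r_squared, "f_value": self.f_value,
                "p_value": self.p_value, "n_fit": self.n_fit}

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuadraticModel":
        return cls(a=float(d["a"]), b=float(d["b"]), c=float(d["c"]),
                   predictor_name=d.get("predictor", "cmp"),
                   group=d.get("group"),
                   r_squared=d.get("r_squared"), f_value=d.get("f_value"),
                   p_value=d.get("p_value"), n_fit=d.get("n_fit"))


def fit_quadratic(x, y, *, predictor_name: str = "cmp",
                  group: str | None = None) -> QuadraticModel:
    """Least-squares quadratic fit of counts on a predictor.

    R^2 = 1 - SSE/SST; F = (SSR/2) / (SSE/(n-3)) with p from F(2, n-3).
    Raises :class:`EstimationError` if the design [x^2, x, 1] is rank
    deficient (constant x, or only two distinct x values).
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise InvalidParameterError(f"x and y lengths differ: {xv.size} != {yv.size}")
    n = xv.size
    if n < 4:
        raise InvalidParameterError(f"need at least 4 points, got {n}")
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
        raise InvalidParameterError("x and y must be finite")
    X = np.column_stack([xv ** 2, xv, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < 3:
        raise EstimationError(
            "singular quadratic design: x is constant or takes only two values")
    fitted = X @ coef
    sse = float(np.sum((yv - fitted) ** 2))
    sst = float(np.sum((yv - yv.mean()) ** 2))
    ssr = max(sst - sse, 0.0)
    r2 = 1.0 if sst == 0.0 else max(0.0, min(1.0, 1.0 - sse / sst))
    tol = 1e-12 * max(sst, 1.0)
    if ssr <= tol:  # no explainable signal, F = 0 even for constant y
        f = 0.0
        p = 1.0
    elif sse <= tol:  # perfect fit with signal
        f = math.inf
        p = 0.0
    else:
        f = (ssr / 2.0) / (sse / (n - 3))
        p = float(stats.f.sf(f, 2, n - 3))
    return QuadraticModel(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                          predictor_name=predictor_name, group=group,
                          r_squared=r2, f_value=f, p_value=p, n_fit=n)


def predict_incidence(model: QuadraticModel, x):
    """Evaluate a*x^2 + b*x + c at scalar or array ``x`` (not clipped).

    Predictions are real-valued; callers may clip at zero for display or
    round before severity classification.
    """
    xv = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xv)):
        raise DomainError(f"predictor value must be finite, got {x!r}")
    out = model.a * xv ** 2 + model.b * xv + model.c
    return float(out) if np.isscalar(x) or xv.ndim == 0 else out


def reference_models() -> dict[str, QuadraticModel]:
    """Published CMP-based incidence models for the three allergen groups.

    Coefficients are fixed study results (predictor = CMP in hPa.degC/hPa
    units); the fit-statistic fields are unset because the underlying
    per-window cohort data are not redistributable.
    """
    spec = {
        "pollen": (404.45, -51.32, 16.88),
        "dust_mite": (47.20, 7.59, 9.36),
        "mould": (7.35, 12.64, 3.17),
    }
    return {g: QuadraticModel(a=a, b=b, c=c, predictor_name="cmp", group=g)
            for g, (a, b, c) in spec.items()}
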