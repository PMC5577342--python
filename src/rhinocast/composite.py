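"""Composite meteorological parameter (CMP).

The CMP condenses three biweekly meteorological means into a single
exposure index per window::

    CMP_i = E_i * TD_i / P_i

where ``E_i`` is the window-mean vapour pressure (hPa), ``TD_i`` the
window-mean daily minimum temperature (degrees C) and ``P_i`` the
window-mean sea-level pressure (hPa).  With these units the index spans
roughly -0.1 to 0.8 over a Beijing-like annual cycle, the scale on which
the quadratic incidence models in :mod:`rhinocast.quadratic` are defined.
Any other unit convention (Kelvin in particular) rescales the index and
invalidates those coefficients, so the units are fixed here and not
configurable.

Negative values (sub-zero window-mean minimum temperature) are legitimate
winter states and are passed through unchanged.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["compute_cmp", "cmp_series"]


def compute_cmp(vapour_hpa: float, tmin_c: float, slp_hpa: float) -> float:
    """Return the composite index E*TD/P for one window.

    Parameters
    ----------
    vapour_hpa : float
        Window-mean vapour pressure E, in hPa; must be >= 0.
    tmin_c : float
        Window-mean daily minimum temperature TD, in degrees Celsius.
    slp_hpa : float
        Window-mean sea-level pressure P, in hPa; must be > 0.

    Raises
    ------
    DomainError
        If P <= 0, E < 0, or any input is non-finite.
    """
    e, td, p = float(vapour_hpa), float(tmin_c), float(slp_hpa)
    if not (math.isfinite(e) and math.isfinite(td) and math.isfinite(p)):
        raise DomainError("CMP inputs must be finite, got "
                          f"E={vapour_hpa!r}, TD={tmin_c!r}, P={slp_hpa!r}")
    if p <= 0.0:
        raise DomainError(f"sea-level pressure must be positive, got {p}")
    if e < 0.0:
        raise DomainError(f"vapour pressure must be non-negative, got {e}")
    return e * td / p


def cmp_series(
    biweekly: pd.DataFrame,
    *,
    vapour_col: str = "vapour_mean",
    tmin_col: str = "tmin_mean",
    slp_col: str = "slp_mean",
) -> pd.Series:
    """Apply :func:`compute_cmp` to every row of a biweekly table.

    Returns a float Series named ``"cmp"`` aligned with ``biweekly``'s
    index.  Domain violations are re-raised with the offending window's
    index attached.
    """
    for col in (vapour_col, tmin_col, slp_col):
        if col not in biweekly.columns:
            raise KeyError(f"biweekly table lacks required column {col!r}")
    e = biweekly[vapour_col].to_numpy(dtype=float)
    td = biweekly[tmin_col].to_numpy(dtype=float)
    p = biweekly[slp_col].to_numpy(dtype=float)

    bad = ~(np.isfinite(e) & np.isfinite(td) & np.isfinite(p))
    bad |= (p <= 0.0) | (e < 0.0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        try:
            compute_cmp(e[i], td[i], p[i])
        except DomainError as err:
            raise DomainError(f"window index {biweekly.index[i]}: {err}") from None
    return pd.Series(e * td / p, index=biweekly.index, name="cmp")
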