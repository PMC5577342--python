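"""Biweekly aggregation of daily visit records and daily meteorology.

The analysis operates on consecutive, non-overlapping, half-open windows
``[start + i*L, start + (i+1)*L)`` of length ``L`` days (default 14).
Visit counts per window are the incidence series; window-mean meteorology
feeds the composite index and the quadratic predictors.

The study-shaped configuration is 92 fortnightly windows anchored at
2007-02-04; all 92 fall inside the 2007-02-04..2010-11-22 observation
span.  The anchor date and the number of windows are explicit
configuration because the original sampling calendar is not fully
determined by the span alone.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingDataError

__all__ = [
    "WindowSpec",
    "study_window_spec",
    "aggregate_visits",
    "average_meteorology",
    "build_biweekly",
    "GROUPS",
]

#: Allergen groups carried through the whole pipeline.
GROUPS = ("pollen", "dust_mite", "mould")

#: Meteorological columns averaged per window (daily-table name -> biweekly name).
MEAN_COLUMNS = {
    "tmin_c": "tmin_mean",
    "vapour_hpa": "vapour_mean",
    "slp_hpa": "slp_mean",
    "tmax_c": "tmax_mean",
    "tavg_c": "tavg_mean",
    "rh_pct": "rh_mean",
    "precip_mm": "precip_mean",
    "wind_ms": "wind_mean",
    "dewpoint_c": "dewpoint_mean",
}


@dataclass(frozen=True)
class WindowSpec:
    """Consecutive half-open aggregation windows.

    Attributes
    ----------
    start_date : datetime.date
        First day of window 0.
    window_length : int
        Window length in days (>= 1); 14 for the biweekly analysis.
    n_windows : int
        Number of consecutive windows (>= 1).
    """

    start_date: dt.date
    window_length: int = 14
    n_windows: int = 92

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise InvalidParameterError(
                f"window_length must be >= 1, got {self.window_length}")
        if self.n_windows < 1:
            raise InvalidParameterError(
                f"n_windows must be >= 1, got {self.n_windows}")

    @property
    def end_date(self) -> dt.date:
        """First day AFTER the last window (half-open overall span)."""
        return self.start_date + dt.timedelta(
            days=self.window_length * self.n_windows)

    def window_start(self, i: int) -> dt.date:
        return self.start_date + dt.timedelta(days=self.window_length * i)

    def window_index(self, date: dt.date) -> int:
        """Window containing ``date``, or -1 if outside all windows.

        A window's upper boundary date belongs to the NEXT window
        (half-open convention); every in-span date maps to exactly one
        window.
        """
        offset = (date - self.start_date).days
        if offset < 0:
            return -1
        i = offset // self.window_length
        return i if i < self.n_windows else -1

    def window_dates(self, i: int) -> pd.DatetimeIndex:
        return pd.date_range(self.window_start(i),
                             periods=self.window_length, freq="D")

    def all_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date,
                             periods=self.window_length * self.n_windows,
                             freq="D")


def study_window_spec() -> WindowSpec:
    """The study-shaped window calendar: 92 fortnights from 2007-02-04."""
    return WindowSpec(start_date=dt.date(2007, 2, 4), window_length=14,
                      n_windows=92)


def _to_dates(series: pd.Series) -> pd.Series:
    try:
        return pd.to_datetime(series, format="ISO8601").dt.date
    except (ValueError, TypeError) as err:
        raise MissingDataError(f"malformed date in visit table: {err}") from None


def aggregate_visits(
    visits: pd.DataFrame,
    spec: WindowSpec,
    group: str,
    *,
    out_of_span: str = "drop",
) -> np.ndarray:
    """Count visits of ``group`` per window.

    Parameters
    ----------
    visits : DataFrame
        Columns ``date`` (ISO-8601 or datetime-like) and ``group``.
    spec : WindowSpec
    group : str
        Allergen group to count.
    out_of_span : {"drop", "error"}
        Policy for visits dated outside all windows: drop with a warning,
        or raise :class:`MissingDataError`.

    Returns
    -------
    ndarray of int, length ``spec.n_windows``
        Windows with no visits hold 0.  The sum equals the number of
        in-span visits of the group (conservation).
    """
    if out_of_span not in ("drop", "error"):
        raise InvalidParameterError(
            f"out_of_span must be 'drop' or 'error', got {out_of_span!r}")
    counts = np.zeros(spec.n_windows, dtype=int)
    sub = visits.loc[visits["group"] == group]
    if sub.empty:
        return counts
    dates = _to_dates(sub["date"])
    idx = np.array([spec.window_index(d) for d in dates], dtype=int)
    n_out = int((idx < 0).sum())
    if n_out:
        if out_of_span == "error":
            raise MissingDataError(
                f"{n_out} visit(s) dated outside all windows "
                f"(span {spec.start_date}..{spec.end_date})")
        warnings.warn(f"dropping {n_out} visit(s) outside the window span",
                      stacklevel=2)
        idx = idx[idx >= 0]
    np.add.at(counts, idx, 1)
    return counts


def average_meteorology(
    daily: pd.DataFrame,
    spec: WindowSpec,
    columns: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Arithmetic per-window means of daily meteorological variables.

    Every day of every window must be present in ``daily``; a missing day
    raises :class:`MissingDataError` naming the date(s) — no imputation.

    Returns a DataFrame indexed by ``window_index`` with one renamed mean
    column per input variable (``tmin_c`` -> ``tmin_mean``, ...), plus a
    ``window_start`` column.
    """
    if "date" not in daily.columns:
        raise MissingDataError("daily meteorology table lacks a 'date' column")
    cols = [c for c in (columns or MEAN_COLUMNS) if c in daily.columns]
    if not cols:
        raise MissingDataError("no known meteorological columns found; "
                               f"expected some of {sorted(MEAN_COLUMNS)}")
    day = pd.to_datetime(daily["date"]).dt.normalize()
    table = daily[cols].set_axis(day).sort_index()
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0].date()
        raise MissingDataError(f"duplicate daily record for {dup}")

    needed = spec.all_dates()
    missing = needed.difference(table.index)
    if len(missing):
        shown = ", ".join(str(d.date()) for d in missing[:5])
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        raise MissingDataError(f"missing daily meteorology for: {shown}{more}")

    aligned = table.reindex(needed).to_numpy(dtype=float)
    split = aligned.reshape(spec.n_windows, spec.window_length, len(cols))
    means = split.mean(axis=1)
    out = pd.DataFrame(means, columns=[MEAN_COLUMNS[c] for c in cols])
    out.insert(0, "window_start",
               [spec.window_start(i) for i in range(spec.n_windows)])
    out.index.name = "window_index"
    return out


def build_biweekly(
    visits: pd.DataFrame,
    daily: pd.DataFrame,
    spec: WindowSpec,
    groups: Sequence[str] = GROUPS,
    *,
    out_of_span: str = "drop",
) -> pd.DataFrame:
    """Join per-window counts and meteorological means into one long table.

    One row per (window, group): ``window_index, window_start, group,
    ar_count`` plus the window-mean meteorology columns.
    """
    meteo = average_meteorology(daily, spec)
    frames = []
    for g in groups:
        counts = aggregate_visits(visits, spec, g, out_of_span=out_of_span)
        block = meteo.reset_index()
        block.insert(2, "group", g)
        block.insert(3, "ar_count", counts)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)
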