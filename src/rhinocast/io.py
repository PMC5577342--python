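"""CSV / JSON readers and writers for the pipeline's artifacts.

All dates are ISO-8601.  Meteorology and visit CSVs use the dialects the
synthetic generator writes; models and evaluation reports are JSON.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import MissingDataError
from .quadratic import QuadraticModel
from .synthetic import METEO_COLUMNS
from .temporal import ARModel

__all__ = [
    "read_meteorology", "write_meteorology",
    "read_visits", "write_visits",
    "read_biweekly", "write_biweekly",
    "save_json", "load_json",
    "save_model", "load_ar_model", "load_quadratic_model",
]

VISIT_COLUMNS = ["date", "group"]


def _require_columns(df: pd.DataFrame, required, what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingDataError(
            f"{what} file {path} is missing column(s): {', '.join(missing)}")


def read_meteorology(path) -> pd.DataFrame:
    """Read a daily meteorology CSV: typed, date-sorted, duplicate-free.

    Rows out of date order are returned sorted; a duplicate date or an
    unparsable value raises :class:`MissingDataError` naming the row.
    """
    df = pd.read_csv(path)
    _require_columns(df, METEO_COLUMNS, "meteorology", path)
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as err:
        raise MissingDataError(f"unparsable date in {path}: {err}") from None
    df = df.copy()
    df["date"] = dates.dt.date
    dup = df["date"].duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise MissingDataError(
            f"duplicate date {df['date'][row]} in {path} (row {row + 2})")
    for col in METEO_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise MissingDataError(
                f"unparsable value in column {col!r} of {path} (row {row + 2})")
        df[col] = vals.astype(float)
    return df.sort_values("date", ignore_index=True)[METEO_COLUMNS]


def write_meteorology(meteo: pd.DataFrame, path) -> None:
    meteo.to_csv(path, index=False, columns=METEO_COLUMNS, float_format="%.4f")


def read_visits(path) -> pd.DataFrame:
    """Read a visit-record CSV (columns ``date, group``)."""
    df = pd.read_csv(path)
    _require_columns(df, VISIT_COLUMNS, "visits", path)
    try:
        df = df.assign(date=pd.to_datetime(df["date"], format="ISO8601").dt.date)
    except (ValueError, TypeError) as err:
        raise MissingDataError(f"unparsable date in {path}: {err}") from None
    return df[VISIT_COLUMNS]


def write_visits(visits: pd.DataFrame, path) -> None:
    visits.to_csv(path, index=False, columns=VISIT_COLUMNS)


def write_biweekly(biweekly: pd.DataFrame, path) -> None:
    biweekly.to_csv(path, index=False)


def read_biweekly(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["window_index", "window_start", "group", "ar_count"],
                     "biweekly", path)
    df["window_start"] = pd.to_datetime(df["window_start"]).dt.date
    return df


def save_json(obj: Mapping, path, *, stamp: Mapping | None = None) -> None:
    """Write a JSON artifact, optionally stamped with run metadata."""
    payload = dict(obj)
    if stamp:
        payload["_run"] = dict(stamp)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (dt.date, dt.datetime)):
        return o.isoformat()
    raise TypeError(f"not JSON-serialisable: {o!r}")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def save_model(model: ARModel | QuadraticModel, path,
               *, stamp: Mapping | None = None) -> None:
    save_json(model.to_dict(), path, stamp=stamp)


def load_ar_model(path) -> ARModel:
    return ARModel.from_dict(load_json(path))


def load_quadratic_model(path) -> QuadraticModel:
    return QuadraticModel.from_dict(load_json(path))
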