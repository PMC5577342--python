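"""Model evaluation: random train/test split, held-out RMSE per
predictor, and the four-level severity classification of biweekly case
counts.

The study design draws a single uniform random subset of ~70% of the
biweekly windows for fitting (67 of 92 in the original calendar) and
scores each (allergen group, predictor) quadratic model by the root mean
squared error of its predictions on the remaining windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EstimationError, InvalidParameterError
from .quadratic import QuadraticModel, fit_quadratic, predict_incidence

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "SEVERITY_BOUNDS",
    "train_test_split",
    "rmse",
    "compare_predictors",
    "classify_level",
]

#: Inclusive integer count bounds of the four severity levels.
SEVERITY_BOUNDS = {
    "I": (0, 16),
    "II": (17, 52),
    "III": (53, 104),
    "IV": (105, None),
}

#: Predictor columns of the standard 3x4 comparison grid.
DEFAULT_PREDICTORS = ("tmin_mean", "slp_mean", "vapour_mean", "cmp")


@dataclass(frozen=True)
class SplitSpec:
    """Uniform random train/test partition of ``n_total`` windows."""

    n_total: int
    n_train: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_train < self.n_total):
            raise InvalidParameterError(
                f"need 0 < n_train < n_total, got {self.n_train}/{self.n_total}")


@dataclass
class EvaluationReport:
    """Held-out RMSE per (group, predictor) plus the split that produced it.

    ``rmse_table`` maps (group, predictor) -> test RMSE; cells whose fit
    failed (singular design) are listed in ``flagged`` and hold NaN.
    """

    rmse_table: dict[tuple[str, str], float]
    split: SplitSpec
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    models: dict[tuple[str, str], QuadraticModel] = field(default_factory=dict)
    flagged: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """The grid as a DataFrame (groups as rows, predictors as columns)."""
        groups = sorted({g for g, _ in self.rmse_table})
        preds = sorted({p for _, p in self.rmse_table})
        data = [[self.rmse_table[(g, p)] for p in preds] for g in groups]
        return pd.DataFrame(data, index=groups, columns=preds)

    def best_predictor(self, group: str) -> str:
        """Predictor with the smallest finite RMSE for ``group``."""
        cells = {p: v for (g, p), v in self.rmse_table.items()
                 if g == group and math.isfinite(v)}
        if not cells:
            raise EstimationError(f"no finite RMSE cells for group {group!r}")
        return min(cells, key=cells.get)

    def to_dict(self) -> dict:
        return {
            "rmse": {g: {p: v for (gg, p), v in self.rmse_table.items() if gg == g}
                     for g in sorted({g for g, _ in self.rmse_table})},
            "flagged": {f"{g}/{p}": msg for (g, p), msg in self.flagged.items()},
            "split": {"n_total": self.split.n_total,
                      "n_train": self.split.n_train,
                      "seed": self.split.seed},
            "train_indices": list(self.train_indices),
            "test_indices": list(self.test_indices),
            "models": {f"{g}/{p}": m.to_dict() for (g, p), m in self.models.items()},
        }


def train_test_split(spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seed-deterministic uniform split without replacement.

    Returns sorted integer index arrays (train, test); they are disjoint
    and together cover 0..n_total-1.
    """
    rng = np.random.default_rng(spec.seed)
    train = np.sort(rng.choice(spec.n_total, size=spec.n_train, replace=False))
    mask = np.ones(spec.n_total, dtype=bool)
    mask[train] = False
    return train, np.flatnonzero(mask)


def rmse(predicted, observed) -> float:
    """Root mean squared error sqrt(mean((predicted - observed)^2))."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise InvalidParameterError(f"length mismatch: {p.size} != {o.size}")
    if p.size == 0:
        raise InvalidParameterError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def compare_predictors(
    biweekly: pd.DataFrame,
    spec: SplitSpec,
    *,
    groups: Sequence[str] | None = None,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
) -> EvaluationReport:
    """Fit each predictor's quadratic on train windows; score test RMSE.

    ``biweekly`` is the long table from :func:`~rhinocast.preprocess.build_biweekly`
    with a ``cmp`` column appended; one row per (window, group).  The same
    window split is shared by every (group, predictor) cell so the cells
    are comparable.  Cells whose quadratic fit is singular are flagged in
    the report, never silently dropped.
    """
    groups = tuple(groups) if groups is not None else tuple(
        pd.unique(biweekly["group"]))
    missing = [c for c in predictors if c not in biweekly.columns]
    if missing:
        raise InvalidParameterError(f"missing predictor columns: {missing}")
    train_idx, test_idx = train_test_split(spec)

    table: dict[tuple[str, str], float] = {}
    models: dict[tuple[str, str], QuadraticModel] = {}
    flagged: dict[tuple[str, str], str] = {}
    for g in groups:
        sub = biweekly.loc[biweekly["group"] == g].sort_values("window_index")
        if len(sub) != spec.n_total:
            raise InvalidParameterError(
                f"group {g!r} has {len(sub)} windows, split expects {spec.n_total}")
        y = sub["ar_count"].to_numpy(dtype=float)
        for p in predictors:
            x = sub[p].to_numpy(dtype=float)
            try:
                model = fit_quadratic(x[train_idx], y[train_idx],
                                      predictor_name=p, group=g)
            except EstimationError as err:
                flagged[(g, p)] = str(err)
                table[(g, p)] = float("nan")
                continue
            models[(g, p)] = model
            table[(g, p)] = rmse(predict_incidence(model, x[test_idx]),
                                 y[test_idx])
    return EvaluationReport(rmse_table=table, split=spec,
                            train_indices=tuple(int(i) for i in train_idx),
                            test_indices=tuple(int(i) for i in test_idx),
                            models=models, flagged=flagged)


def classify_level(count) -> str:
    """Severity level I-IV of a biweekly AR case count.

    Real-valued predictions are rounded half-up first.  Levels partition
    the non-negative integers: I = 0..16, II = 17..52, III = 53..104,
    IV >= 105.
    """
    c = float(count)
    if not math.isfinite(c):
        raise DomainError(f"count must be finite, got {count!r}")
    if c < 0:
        raise DomainError(f"count must be non-negative, got {count!r}")
    k = math.floor(c + 0.5)  # round half-up
    for level, (lo, hi) in SEVERITY_BOUNDS.items():
        if k >= lo and (hi is None or k <= hi):
            return level
    raise AssertionError("unreachable: levels partition the non-negative integers")
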