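"""Declarative configuration and end-to-end pipeline orchestration.

A single config (YAML file or :class:`PipelineConfig`) drives the whole
analysis in order: simulate/load daily data -> biweekly aggregation ->
autoregressive trend fit + white-noise residual check -> composite index
-> quadratic incidence fits -> train/test RMSE comparison -> severity
classification.  Every stochastic stage draws its seed deterministically
from the one global seed, so any stage re-runs reproducibly in
isolation, and every artifact is stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as rcio
from .composite import cmp_series
from .errors import InvalidParameterError
from .evaluate import DEFAULT_PREDICTORS, SplitSpec, classify_level, compare_predictors
from .preprocess import GROUPS, WindowSpec, build_biweekly
from .quadratic import fit_quadratic
from .synthetic import (IncidenceSimParams, MeteoSimParams,
                        default_incidence_params, generate_incidence,
                        generate_meteorology)
from .temporal import fit_ar, select_order, white_noise_test

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("rhinocast")

_STAGES = ("simulate_meteo", "simulate_visits", "split")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full run."""

    seed: int = 0
    out_dir: str = "rhinocast_run"
    # window calendar
    start_date: dt.date = dt.date(2007, 2, 4)
    window_length: int = 14
    n_windows: int = 92
    # inputs: simulate, or read from files
    simulate: bool = True
    meteo_csv: str | None = None
    visits_csv: str | None = None
    meteo_params: MeteoSimParams | None = None
    incidence_params: Mapping[str, IncidenceSimParams] | None = None
    # modelling
    groups: Sequence[str] = GROUPS
    trend_lags: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {"pollen": (1, 4), "dust_mite": (1, 2),
                                 "mould": (1,)})
    auto_order: bool = False
    max_p: int = 5
    max_q: int = 5
    white_noise_lags: int = 12
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    n_train: int = 67
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [g for g in self.groups if g not in GROUPS]
        if unknown:
            raise InvalidParameterError(
                f"unknown group(s) {unknown}; known groups: {list(GROUPS)}")
        if not self.simulate and (self.meteo_csv is None or self.visits_csv is None):
            raise InvalidParameterError(
                "simulate=False requires meteo_csv and visits_csv")
        if not (0 < self.n_train < self.n_windows):
            raise InvalidParameterError(
                f"need 0 < n_train < n_windows, got {self.n_train}/{self.n_windows}")
        for g, lags in self.trend_lags.items():
            if g not in GROUPS:
                raise InvalidParameterError(f"trend_lags for unknown group {g!r}")
            if any(int(k) != k or k < 1 for k in lags):
                raise InvalidParameterError(f"invalid lags for {g!r}: {lags}")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.start_date, self.window_length, self.n_windows)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        if self.meteo_params is not None:
            mp = dataclasses.asdict(self.meteo_params)
            mp["start_date"] = self.meteo_params.start_date.isoformat()
            mp["noise_sd"] = dict(self.meteo_params.noise_sd)
            d["meteo_params"] = mp
        if self.incidence_params is not None:
            d["incidence_params"] = {
                g: dataclasses.asdict(p) for g, p in self.incidence_params.items()}
        d["groups"] = list(self.groups)
        d["predictors"] = list(self.predictors)
        d["trend_lags"] = {g: list(v) for g, v in self.trend_lags.items()}
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (presentation fields —
        output directory, log level — excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        kwargs = dict(raw)
        if "start_date" in kwargs and isinstance(kwargs["start_date"], str):
            kwargs["start_date"] = dt.date.fromisoformat(kwargs["start_date"])
        if isinstance(kwargs.get("meteo_params"), Mapping):
            mp = dict(kwargs["meteo_params"])
            if isinstance(mp.get("start_date"), str):
                mp["start_date"] = dt.date.fromisoformat(mp["start_date"])
            kwargs["meteo_params"] = MeteoSimParams(**mp)
        if isinstance(kwargs.get("incidence_params"), Mapping):
            kwargs["incidence_params"] = {
                g: IncidenceSimParams(**{**p, "group": g})
                for g, p in kwargs["incidence_params"].items()}
        if isinstance(kwargs.get("trend_lags"), Mapping):
            kwargs["trend_lags"] = {g: tuple(v)
                                    for g, v in kwargs["trend_lags"].items()}
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt_s = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, dt_s)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt_s, exc)
            return False
    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage in order and write all artifacts under ``out_dir``.

    Returns a mapping from artifact name to path.  Outputs are a pure
    function of (input files, config, seed): re-running with the same
    configuration reproduces them byte for byte.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.window_spec
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    artifacts: dict[str, Path] = {}

    with _timed("input"):
        if config.simulate:
            mp = config.meteo_params or MeteoSimParams(
                start_date=config.start_date,
                n_days=config.window_length * config.n_windows,
                seed=stage_seed(config.seed, "simulate_meteo"))
            meteo = generate_meteorology(mp)
            inc = config.incidence_params or default_incidence_params(
                seed=stage_seed(config.seed, "simulate_visits"))
            visits = pd.concat(
                [generate_incidence(meteo, inc[g], spec) for g in config.groups
                 if g in inc], ignore_index=True)
            artifacts["meteorology"] = out / "meteorology.csv"
            artifacts["visits"] = out / "visits.csv"
            rcio.write_meteorology(meteo, artifacts["meteorology"])
            rcio.write_visits(visits, artifacts["visits"])
        else:
            meteo = rcio.read_meteorology(config.meteo_csv)
            visits = rcio.read_visits(config.visits_csv)
        log.info("input: %d daily records, %d visits", len(meteo), len(visits))

    with _timed("aggregate"):
        biweekly = build_biweekly(visits, meteo, spec, groups=config.groups)
        biweekly["cmp"] = cmp_series(biweekly)
        artifacts["biweekly"] = out / "biweekly.csv"
        rcio.write_biweekly(biweekly, artifacts["biweekly"])

    with _timed("trend"):
        for g in config.groups:
            series = (biweekly.loc[biweekly["group"] == g]
                      .sort_values("window_index")["ar_count"]
                      .to_numpy(dtype=float))
            if config.auto_order:
                p, q = select_order(series, config.max_p, config.max_q)
                lags = tuple(range(1, p + 1)) if p else ()
                log.info("trend %s: BIC order (p=%d, q=%d)", g, p, q)
            else:
                lags = tuple(config.trend_lags.get(g, (1,)))
            if lags:
                model = fit_ar(series, lags, group=g)
                d = series - model.series_mean
                m = model.max_lag
                resid = d[m:] - np.column_stack(
                    [d[m - k:len(d) - k] for k in model.lags]) @ np.asarray(
                        model.coefficients)
                model_df = len(model.lags)
            else:  # white-noise trend: no serial structure selected
                from .temporal import ARModel
                model = ARModel((), (), series_mean=float(series.mean()),
                                innovation_sd=float(series.std(ddof=1)), group=g)
                resid = series - model.series_mean
                model_df = 0
            wn = white_noise_test(resid, config.white_noise_lags,
                                  model_df=model_df)
            payload = model.to_dict()
            payload["white_noise"] = {"statistic": wn.statistic, "dof": wn.dof,
                                      "p_value": wn.p_value,
                                      "n_lags": config.white_noise_lags}
            artifacts[f"trend_{g}"] = out / f"trend_{g}.json"
            rcio.save_json(payload, artifacts[f"trend_{g}"], stamp=stamp)

    with _timed("quadratic_fits"):
        for g in config.groups:
            sub = biweekly.loc[biweekly["group"] == g].sort_values("window_index")
            fits = {}
            for p in config.predictors:
                qm = fit_quadratic(sub[p].to_numpy(dtype=float),
                                   sub["ar_count"].to_numpy(dtype=float),
                                   predictor_name=p, group=g)
                fits[p] = qm.to_dict()
            artifacts[f"models_{g}"] = out / f"models_{g}.json"
            rcio.save_json(fits, artifacts[f"models_{g}"], stamp=stamp)

    with _timed("evaluate"):
        split = SplitSpec(n_total=config.n_windows, n_train=config.n_train,
                          seed=stage_seed(config.seed, "split"))
        report = compare_predictors(biweekly, split, groups=config.groups,
                                    predictors=config.predictors)
        artifacts["evaluation"] = out / "evaluation.json"
        rcio.save_json(report.to_dict(), artifacts["evaluation"], stamp=stamp)

    with _timed("classify"):
        rows = []
        for g in config.groups:
            best = report.best_predictor(g)
            model = report.models[(g, best)]
            sub = biweekly.loc[biweekly["group"] == g].sort_values("window_index")
            pred = np.maximum(model.predict(sub[best].to_numpy(dtype=float)), 0.0)
            for (_, row), yhat in zip(sub.iterrows(), pred):
                rows.append({
                    "window_index": int(row["window_index"]),
                    "window_start": row["window_start"],
                    "group": g,
                    "predictor": best,
                    "observed_count": int(row["ar_count"]),
                    "predicted_count": round(float(yhat), 3),
                    "observed_level": classify_level(row["ar_count"]),
                    "predicted_level": classify_level(yhat),
                })
        levels = pd.DataFrame(rows)
        artifacts["levels"] = out / "levels.csv"
        levels.to_csv(artifacts["levels"], index=False)

    manifest = {"config": config.to_dict(), "config_hash": stamp["config_hash"],
                "seed": config.seed,
                "artifacts": {k: str(v) for k, v in artifacts.items()}}
    artifacts["manifest"] = out / "manifest.json"
    rcio.save_json(manifest, artifacts["manifest"])
    return artifacts
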