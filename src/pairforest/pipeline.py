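"""End-to-end orchestration: simulate -> split -> match -> pairs -> forests ->
forecast -> evaluate.

Every stochastic stage derives its seed from the single run seed, so a rerun
with the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import (
    Cohort,
    ForecastRow,
    read_cohort,
    write_cohort,
    write_forecasts,
)
from .forecaster import (
    ForestConfig,
    ImportanceReport,
    TrainedModel,
    predict_dx,
    predict_interval,
    predict_vents_icv,
    train,
    tune,
    variable_importance,
)
from .matching import MatchResult, match_evaluation_set, write_match_result
from .metrics import ConfusionMatrix, MetricsReport, evaluate_forecasts
from .pairwise import (
    FeatureSpec,
    PairSample,
    build_forecast_inputs,
    build_pairs,
    filter_min_length,
    impute_missing,
)
from .simulate import SimParams, simulate, split_lb

logger = logging.getLogger("pairforest")

#: Seed offsets so each model sees a distinct but derived stream.
_SEED_OFFSET = {"DIAGNOSIS": 11, "ADAS13": 23, "VENTS": 37, "ICV": 53}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for the CLI exit message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    min_points: int = 4  # minimum series length for training participants
    horizon_offsets: tuple[int, ...] = tuple(range(1, 85))  # months past last history visit
    tolerance: float = 3.0  # truth-to-forecast month-matching window
    tune: bool = False
    sim: SimParams = field(default_factory=SimParams)
    forest: ForestConfig = field(default_factory=ForestConfig)
    features: Mapping[str, Sequence[str]] | None = None  # per-target overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimParams(**raw.pop("sim", {}))
        forest = ForestConfig(**raw.pop("forest", {}))
        if "horizon_offsets" in raw:
            raw["horizon_offsets"] = tuple(raw["horizon_offsets"])
        return cls(sim=sim, forest=forest, **raw)

    def spec_for(self, target: str) -> FeatureSpec:
        if self.features and target in self.features:
            return FeatureSpec(target=target, feature_names=tuple(self.features[target]))
        return FeatureSpec.default(target)


@dataclass
class PipelineResult:
    report: MetricsReport
    confusion: ConfusionMatrix | None
    forecasts: list[ForecastRow]
    models: dict[str, TrainedModel]
    importances: dict[str, ImportanceReport]
    match_result: MatchResult | None = None
    tuned: dict[str, tuple[int, int]] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # surface the failing stage by name
            raise PipelineError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def default_horizons(history: Cohort, offsets: Sequence[int]) -> dict[int, list[float]]:
    """Forecast months per participant: each offset past the last history visit."""
    return {
        p.rid: [p.last_visit().month + float(o) for o in offsets] for p in history
    }


def train_models(
    train_cohort: Cohort,
    config: RunConfig,
) -> tuple[dict[str, TrainedModel], dict[str, list[PairSample]], dict[str, tuple[int, int]]]:
    """Build pairs and fit one forest per target; returns models, the imputed
    training pairs (the imputation reference for forecast inputs), and the
    hyperparameters used per target."""
    filtered = filter_min_length(train_cohort, config.min_points)
    if len(filtered) == 0:
        raise ValueError(
            f"no training participant has >= {config.min_points} visits"
        )
    models: dict[str, TrainedModel] = {}
    references: dict[str, list[PairSample]] = {}
    used: dict[str, tuple[int, int]] = {}
    for target in ("DIAGNOSIS", "ADAS13", "VENTS", "ICV"):
        spec = config.spec_for(target)
        pairs = build_pairs(filtered, spec)
        if not pairs:
            raise ValueError(f"no training pairs for target {target}")
        imputed = impute_missing(pairs, pairs)
        fc = replace(
            config.forest, seed=(config.seed + _SEED_OFFSET[target]) % (2**31)
        )
        task = "classify_dx" if target == "DIAGNOSIS" else "regress"
        if config.tune:
            fc = tune(imputed, fc, task)
        logger.info(
            "target %s: %d pairs, n_trees=%d min_leaf=%d",
            target, len(imputed), fc.n_trees, fc.min_leaf,
        )
        models[target] = train(imputed, fc, task)
        references[target] = imputed
        used[target] = (fc.n_trees, fc.min_leaf)
    return models, references, used


def forecast(
    models: Mapping[str, TrainedModel],
    references: Mapping[str, Sequence[PairSample]],
    history: Cohort,
    horizons: Mapping[int, Sequence[float]],
    config: RunConfig,
) -> list[ForecastRow]:
    """Predict all requested (rid, month) points and assemble forecast rows."""
    inputs: dict[str, list[PairSample]] = {}
    for target in ("DIAGNOSIS", "ADAS13", "VENTS", "ICV"):
        spec = config.spec_for(target)
        raw = build_forecast_inputs(history, horizons, spec)
        inputs[target] = impute_missing(raw, references[target])

    probs = predict_dx(models["DIAGNOSIS"], inputs["DIAGNOSIS"])
    probs = probs / probs.sum(axis=1, keepdims=True)
    adas = predict_interval(models["ADAS13"], inputs["ADAS13"])
    ratio = predict_vents_icv(
        models["VENTS"], models["ICV"], inputs["VENTS"], inputs["ICV"]
    )

    rows = []
    keys = [(s.rid, s.source_month + s.delta_t) for s in inputs["DIAGNOSIS"]]
    for k, (rid, month) in enumerate(keys):
        rows.append(
            ForecastRow(
                rid=rid,
                forecast_month=month,
                p_nl=float(probs[k, 0]),
                p_mci=float(probs[k, 1]),
                p_ad=float(probs[k, 2]),
                adas13=float(adas[k, 0]),
                adas13_lo=float(adas[k, 1]),
                adas13_hi=float(adas[k, 2]),
                vents_icv=float(ratio[k, 0]),
                vents_icv_lo=float(ratio[k, 1]),
                vents_icv_hi=float(ratio[k, 2]),
            )
        )
    return rows


def carry_forward_forecast(
    history: Cohort, horizons: Mapping[int, Sequence[float]]
) -> list[ForecastRow]:
    """Last-observation baseline: last diagnosis with probability 1, last
    observed ADAS-13 and ventricle ratio as degenerate-interval points.

    Test plumbing for comparisons, not part of the forecasting method.
    """
    from .pairwise import DX_CODE

    rows = []
    for rid, months in horizons.items():
        p = history.by_rid(rid)
        dxs = [v.diagnosis for v in p.visits if v.diagnosis is not None]
        probs = [1 / 3, 1 / 3, 1 / 3]
        if dxs:
            probs = [0.0, 0.0, 0.0]
            probs[int(DX_CODE[dxs[-1]])] = 1.0
        adas_vals = [v.measurements["ADAS13"] for v in p.visits if "ADAS13" in v.measurements]
        adas = adas_vals[-1] if adas_vals else 0.0
        ratios = [
            v.measurements["VENTRICLES"] / v.measurements["ICV"]
            for v in p.visits
            if "VENTRICLES" in v.measurements and "ICV" in v.measurements
        ]
        ratio = ratios[-1] if ratios else 0.02
        for m in months:
            rows.append(
                ForecastRow(
                    rid=rid,
                    forecast_month=float(m),
                    p_nl=probs[0],
                    p_mci=probs[1],
                    p_ad=probs[2],
                    adas13=adas,
                    adas13_lo=adas,
                    adas13_hi=adas,
                    vents_icv=ratio,
                    vents_icv_lo=ratio,
                    vents_icv_hi=ratio,
                )
            )
    return rows


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    cohorts: tuple[Cohort, Cohort, Cohort] | None = None,
) -> PipelineResult:
    """Execute the full chain; optionally on pre-built (train, history, test).

    When ``out_dir`` is given, writes the split CSVs, the match table, the
    forecast CSV, per-target importance JSON and the metrics JSON there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if cohorts is None:
        sim = replace(config.sim, seed=config.seed)
        cohort, _truth = _stage("simulate")(simulate, sim)
        train_c, history_c, test_c = _stage("split")(split_lb, cohort, sim)
    else:
        train_c, history_c, test_c = cohorts

    if out is not None:
        write_cohort(train_c, out / "train.csv")
        write_cohort(history_c, out / "history.csv")
        write_cohort(test_c, out / "test.csv")

    match_result = _stage("match")(match_evaluation_set, train_c, history_c)
    logger.info(
        "matched %d of %d history participants",
        len(match_result.pairs), len(history_c),
    )
    if out is not None:
        write_match_result(match_result, out / "matches.csv")

    models, references, used = _stage("build-pairs/train")(
        train_models, train_c, config
    )

    horizons = default_horizons(history_c, config.horizon_offsets)
    rows = _stage("forecast")(forecast, models, references, history_c, horizons, config)
    if out is not None:
        write_forecasts(rows, out / "forecasts.csv")

    report, cm = _stage("evaluate")(evaluate_forecasts, rows, test_c, config.tolerance)

    importances = {
        target: variable_importance(models[target], references[target])
        for target in models
    }
    if out is not None:
        (out / "metrics.json").write_text(report.to_json())
        (out / "importance.json").write_text(
            json.dumps({t: r.scores for t, r in importances.items()}, indent=2)
        )
        if cm is not None:
            (out / "confusion.json").write_text(
                json.dumps(
                    {
                        "counts": cm.counts.tolist(),
                        "overall_accuracy": cm.overall_accuracy,
                        "per_class_accuracy": cm.per_class_accuracy.tolist(),
                    },
                    indent=2,
                )
            )

    return PipelineResult(
        report=report,
        confusion=cm,
        forecasts=rows,
        models=models,
        importances=importances,
        match_result=match_result,
        tuned=used,
    )
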