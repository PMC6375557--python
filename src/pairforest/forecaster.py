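"""Random-forest learners over pairwise samples.

One three-class classifier predicts the diagnosis at the destination visit;
separate regressors predict ADAS-13, ventricle volume and intracranial volume
(the ventricles/ICV ratio is formed from the two volume predictions).  Trees
use bootstrap samples of size n, consider ceil(sqrt(p)) of the p features at
each split, and stop at a minimum leaf size; hyperparameters (number of
trees, minimum leaf size) are selected by minimizing the out-of-bag (OOB)
error over a grid.  Class probabilities are the ensemble average of per-tree
leaf class proportions; 50% prediction intervals come from the 25th/75th
percentiles of the per-tree regression predictions.  Variable importance is
the OOB permutation importance: the increase in a tree's OOB error when one
feature's values are permuted, averaged over trees and divided by its
standard deviation across trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import mean_squared_error

from .cohort import DIAGNOSES
from .pairwise import DX_CODE, PairSample

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters and the OOB tuning grid."""

    n_trees: int = 60
    min_leaf: int = 5
    features_per_split: str = "sqrt"  # ceil(sqrt(p)) features tried per split
    seed: int = 0
    grid_n_trees: tuple[int, ...] = (20, 40, 60, 80, 100)
    grid_min_leaf: tuple[int, ...] = (1, 5, 10, 25)

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValueError("n_trees and min_leaf must be >= 1")
        if self.features_per_split != "sqrt":
            raise ValueError("only the sqrt features-per-split rule is supported")


@dataclass
class TrainedModel:
    task: str  # "classify_dx" | "regress"
    feature_names: tuple[str, ...]
    ensemble: object
    oob_error: float
    seed: int

    def _check_schema(self, samples: Sequence[PairSample]) -> None:
        for s in samples:
            if tuple(s.features.keys()) != self.feature_names:
                raise ValueError(
                    f"feature-name mismatch: model expects {self.feature_names}, "
                    f"sample has {tuple(s.features.keys())}"
                )


@dataclass
class ImportanceReport:
    """Per-feature permutation importance (mean/SD over trees)."""

    scores: dict[str, float] = field(default_factory=dict)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.scores.items(), key=lambda kv: -kv[1])


def to_matrix(samples: Sequence[PairSample], feature_names: Sequence[str]) -> np.ndarray:
    """Stack sample features into a dense float matrix; missing values are an error."""
    X = np.empty((len(samples), len(feature_names)), dtype=float)
    for i, s in enumerate(samples):
        for j, name in enumerate(feature_names):
            v = s.features.get(name)
            if v is None:
                raise ValueError(
                    f"sample {i} (rid {s.rid}) has missing feature {name!r}; impute first"
                )
            X[i, j] = v
    return X


def _targets(samples: Sequence[PairSample], task: str) -> np.ndarray:
    if task == "classify_dx":
        y = np.empty(len(samples), dtype=int)
        for i, s in enumerate(samples):
            if s.target_dx is None:
                raise ValueError(f"sample {i} has no diagnosis target")
            y[i] = int(DX_CODE[s.target_dx])
        return y
    y = np.empty(len(samples), dtype=float)
    for i, s in enumerate(samples):
        if s.target_value is None:
            raise ValueError(f"sample {i} has no regression target")
        y[i] = s.target_value
    return y


def _max_features(p: int) -> int:
    return max(1, math.ceil(math.sqrt(p)))


def _fit_forest(X: np.ndarray, y: np.ndarray, config: ForestConfig, task: str):
    """Fit one forest and return (ensemble, oob_error)."""
    common = dict(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_leaf,
        max_features=_max_features(X.shape[1]),
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    import warnings

    with warnings.catch_warnings():
        # few trees on tiny data can leave some samples never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")
        if task == "classify_dx":
            if len(np.unique(y)) < 2:
                # degenerate one-class problem: OOB accuracy is trivially 1
                forest = RandomForestClassifier(**{**common, "oob_score": False})
                forest.fit(X, y)
                return forest, 0.0
            forest = RandomForestClassifier(**common)
            forest.fit(X, y)
            return forest, float(1.0 - forest.oob_score_)
        forest = RandomForestRegressor(**{**common, "oob_score": mean_squared_error})
        forest.fit(X, y)
        return forest, float(forest.oob_score_)


def train(samples: Sequence[PairSample], config: ForestConfig, task: str) -> TrainedModel:
    """Fit a forest on fully imputed pairwise samples.

    The stored OOB error is the misclassification rate for the classifier and
    the mean squared error for regressors.  Training is deterministic given
    the samples, the config and its seed.
    """
    if task not in ("classify_dx", "regress"):
        raise ValueError(f"unknown task {task!r}")
    if not samples:
        raise ValueError("no training samples")
    feature_names = tuple(samples[0].features.keys())
    X = to_matrix(samples, feature_names)
    y = _targets(samples, task)
    ensemble, oob = _fit_forest(X, y, config, task)
    return TrainedModel(
        task=task,
        feature_names=feature_names,
        ensemble=ensemble,
        oob_error=oob,
        seed=config.seed,
    )


def tune(samples: Sequence[PairSample], config: ForestConfig, task: str) -> ForestConfig:
    """Grid-search (n_trees, min_leaf) by OOB error.

    Ties prefer the smaller minimum leaf, then the smaller ensemble.  Grid
    points whose leaf size exceeds the sample count are skipped; if every
    point is skipped this is an error.
    """
    if len(samples) < 50:
        raise ValueError("need at least 50 samples to tune by OOB error")
    feature_names = tuple(samples[0].features.keys())
    X = to_matrix(samples, feature_names)
    y = _targets(samples, task)
    best = None
    best_key = None
    for n_trees, min_leaf in product(config.grid_n_trees, config.grid_min_leaf):
        if min_leaf > len(samples):
            continue
        cand = replace(config, n_trees=n_trees, min_leaf=min_leaf)
        _, oob = _fit_forest(X, y, cand, task)
        key = (oob, min_leaf, n_trees)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    if best is None:
        raise ValueError("no feasible grid point: every min_leaf exceeds the sample count")
    return best


def predict_dx(model: TrainedModel, samples: Sequence[PairSample]) -> np.ndarray:
    """(n, 3) class probabilities over NL/MCI/AD, rows summing to 1."""
    if model.task != "classify_dx":
        raise ValueError("model is not a diagnosis classifier")
    model._check_schema(samples)
    X = to_matrix(samples, model.feature_names)
    raw = model.ensemble.predict_proba(X)
    probs = np.zeros((len(samples), len(DIAGNOSES)))
    for col, cls in enumerate(model.ensemble.classes_):
        probs[:, int(cls)] = raw[:, col]
    return probs


def predict_interval(
    model: TrainedModel,
    samples: Sequence[PairSample],
    level: float = 0.5,
) -> np.ndarray:
    """(n, 3) array of (point, lo, hi) for a central prediction interval.

    The point estimate is the ensemble mean; the bounds are the per-tree
    prediction percentiles at (1 -/+ level)/2 (linear interpolation).  The
    interval is widened if needed so it always contains the point.
    """
    if model.task != "regress":
        raise ValueError("model is not a regressor")
    if not 0.0 < level < 1.0:
        raise ValueError("interval level must be in (0, 1)")
    model._check_schema(samples)
    X = to_matrix(samples, model.feature_names)
    per_tree = np.stack([tree.predict(X) for tree in model.ensemble.estimators_])
    point = per_tree.mean(axis=0)
    lo = np.percentile(per_tree, 100.0 * (1.0 - level) / 2.0, axis=0)
    hi = np.percentile(per_tree, 100.0 * (1.0 + level) / 2.0, axis=0)
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    return np.column_stack([point, lo, hi])


def predict_vents_icv(
    vents_model: TrainedModel,
    icv_model: TrainedModel,
    vents_samples: Sequence[PairSample],
    icv_samples: Sequence[PairSample],
    level: float = 0.5,
) -> np.ndarray:
    """Ratio forecast: ventricle volume / intracranial volume with interval.

    The two volumes are predicted by separate models (they use different
    feature sets), then combined: point = vents_point / icv_point, interval
    [vents_lo / icv_hi, vents_hi / icv_lo], clipped at 0.
    """
    if len(vents_samples) != len(icv_samples):
        raise ValueError("vents and icv sample lists must align")
    v = predict_interval(vents_model, vents_samples, level)
    icv = predict_interval(icv_model, icv_samples, level)
    if (icv <= 0).any():
        raise ValueError("non-positive intracranial-volume prediction")
    point = v[:, 0] / icv[:, 0]
    lo = np.clip(v[:, 1] / icv[:, 2], 0.0, None)
    hi = v[:, 2] / icv[:, 1]
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    return np.column_stack([point, lo, hi])


# ---------------------------------------------------------------------------
# OOB permutation importance
# ---------------------------------------------------------------------------


def _inbag_indices(tree, n_samples: int) -> np.ndarray:
    # replicates the forest's bootstrap draw: each tree's random_state seeds
    # a RandomState whose first n_samples ints are the in-bag indices
    rs = np.random.RandomState(tree.random_state)
    return rs.randint(0, n_samples, n_samples, dtype=np.int32)


def _tree_error(tree, X: np.ndarray, y: np.ndarray, task: str) -> float:
    pred = tree.predict(X)
    if task == "classify_dx":
        return float(np.mean(pred != y))
    return float(np.mean((pred - y) ** 2))


def variable_importance(model: TrainedModel, samples: Sequence[PairSample]) -> ImportanceReport:
    """OOB permutation importance, averaged over trees and scaled by the SD.

    For each tree, the error on its out-of-bag samples is computed before and
    after permuting one feature's values among those samples; the feature's
    score is the mean error increase over trees divided by its standard
    deviation across trees.  A single-tree ensemble (or a feature whose error
    increase never varies) falls back to the raw mean increase; features the
    forest never uses score 0.  Permutations are seeded from the model seed.
    """
    model._check_schema(samples)
    X = to_matrix(samples, model.feature_names)
    y = _targets(samples, model.task)
    n = len(samples)
    trees = model.ensemble.estimators_
    increases = []  # one row per tree with OOB samples
    for t_idx, tree in enumerate(trees):
        inbag = _inbag_indices(tree, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[inbag] = False
        if not oob_mask.any():
            continue
        X_oob = X[oob_mask]
        y_oob = y[oob_mask]
        base = _tree_error(tree, X_oob, y_oob, model.task)
        rng = np.random.RandomState((model.seed + 7919 * (t_idx + 1)) % (2**31))
        row = np.empty(len(model.feature_names))
        for f in range(len(model.feature_names)):
            X_perm = X_oob.copy()
            X_perm[:, f] = X_perm[rng.permutation(X_perm.shape[0]), f]
            row[f] = _tree_error(tree, X_perm, y_oob, model.task) - base
        increases.append(row)
    if not increases:
        return ImportanceReport(scores={name: 0.0 for name in model.feature_names})
    D = np.vstack(increases)
    means = D.mean(axis=0)
    if D.shape[0] > 1:
        sds = D.std(axis=0, ddof=1)
    else:
        sds = np.zeros(D.shape[1])
    scores = np.where(sds > 0, means / np.where(sds > 0, sds, 1.0), means)
    return ImportanceReport(scores=dict(zip(model.feature_names, scores.tolist())))


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "task": model.task,
            "feature_names": list(model.feature_names),
            "oob_error": model.oob_error,
            "seed": model.seed,
            "ensemble": model.ensemble,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {payload.get('format_version')}")
    return TrainedModel(
        task=payload["task"],
        feature_names=tuple(payload["feature_names"]),
        ensemble=payload["ensemble"],
        oob_error=payload["oob_error"],
        seed=payload["seed"],
    )
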