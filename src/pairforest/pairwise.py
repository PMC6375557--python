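"""Pairwise sample construction from irregular time series.

The forecasting model treats each ordered pair of visits (i, j), month_i <
month_j, of one participant as a training instance: the input is a summary of
the series up to visit i (last diagnosis, current measurements, slopes of past
measurements, static covariates) together with the time delay
``TIME_DELAY = month_j - month_i``, and the target is the outcome observed at
visit j.  Formally the outcome g_t is modelled as
``g_t = f(lambda, g_{t - dt}, dt) + eps_t`` where lambda are the static
covariates — so irregular sampling and short series need no interpolation or
distributional assumptions: every forward visit pair contributes one sample at
its own time separation.

Feature engineering: MMSE enters as a binary indicator (raw score >= 26, the
conventional normal-cognition cut), slope features (Delta-prefixed) are
ordinary least-squares slopes over all observations up to the source visit,
age is the age at the source visit, and the participant identifier RID is
itself a feature (it carries individual-specific information for participants
seen in training).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import Cohort, ParticipantSeries, Visit

#: Targets a model can be trained for.
TARGETS = ("DIAGNOSIS", "ADAS13", "VENTS", "ICV")

#: Fixed ordinal encodings (deterministic forests need stable numeric inputs).
DX_CODE = {"NL": 0.0, "MCI": 1.0, "AD": 2.0}
GENDER_CODE = {"female": 0.0, "male": 1.0}

SLOPE_PREFIX = "Δ"

#: Slope feature -> underlying raw measurement.
SLOPE_BASE = {
    "ΔMMSE": "MMSE",
    "ΔADAS13": "ADAS13",
    "ΔHIPPOCAMPUS": "HIPPOCAMPUS",
    "ΔVENTRICLES": "VENTRICLES",
    "ΔICV": "ICV",
}

#: Time-varying (per-visit) non-slope features.
TIME_VARYING = ("DX", "MMSE", "CDRSB", "FAQ", "MIDTEMP", "ADAS13", "ICV", "VENTRICLES")

#: Features treated as categorical by the imputer.
CATEGORICAL = ("DX", "GENDER")

#: Measurement supplying the regression target for each target kind.
TARGET_MEASUREMENT = {"ADAS13": "ADAS13", "VENTS": "VENTRICLES", "ICV": "ICV"}

_SHARED = [
    "DX",
    "AGE",
    "GENDER",
    "APOE",
    "MMSE",
    "CDRSB",
    "FAQ",
    "RID",
    "MIDTEMP",
    "TIME_DELAY",
    "ΔMMSE",
    "ΔHIPPOCAMPUS",
    "ΔVENTRICLES",
]

#: Default feature sets per target: the diagnosis set, the diagnosis set plus
#: ADAS13 and its slope for ADAS-13 regression, and minimal last-value +
#: slope + delay sets for the two volume models whose ratio gives VENTS-ICV.
DEFAULT_FEATURES: dict[str, list[str]] = {
    "DIAGNOSIS": list(_SHARED),
    "ADAS13": [*_SHARED, "ADAS13", "ΔADAS13"],
    "VENTS": ["VENTRICLES", "ΔVENTRICLES", "TIME_DELAY"],
    "ICV": ["ICV", "ΔICV", "TIME_DELAY"],
}


@dataclass(frozen=True)
class FeatureSpec:
    """Which target to predict and which named features feed the forest."""

    target: str
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if "TIME_DELAY" not in self.feature_names:
            raise ValueError("TIME_DELAY must be among the features")
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @classmethod
    def default(cls, target: str) -> "FeatureSpec":
        if target not in DEFAULT_FEATURES:
            raise ValueError(f"unknown target {target!r}")
        return cls(target=target, feature_names=tuple(DEFAULT_FEATURES[target]))

    @property
    def required_time_varying(self) -> tuple[str, ...]:
        return tuple(f for f in self.feature_names if f in TIME_VARYING)


@dataclass
class PairSample:
    """One (history summary, time delay) -> outcome instance.

    ``features`` maps each FeatureSpec name to a float or ``None`` (missing);
    diagnosis and gender are already ordinally encoded.  Exactly one of
    ``target_dx`` / ``target_value`` is meaningful depending on the target;
    both are ``None`` for forecast inputs.
    """

    rid: int
    source_month: float
    delta_t: float
    features: dict[str, float | None]
    target_dx: str | None = None
    target_value: float | None = None


def filter_min_length(cohort: Cohort, min_points: int) -> Cohort:
    """Keep only participants with at least ``min_points`` visits."""
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    kept = [p for p in cohort if len(p.visits) >= min_points]
    return Cohort(participants=kept, name=cohort.name)


def binarize_mmse(raw: float | None) -> float | None:
    """Threshold the raw MMSE score at 26: >= 26 -> 1 (unimpaired), else 0."""
    if raw is None:
        return None
    if not 0 <= raw <= 30:
        raise ValueError(f"MMSE out of range: {raw}")
    return 1.0 if raw >= 26 else 0.0


def compute_slope(points: Sequence[tuple[float, float]]) -> float | None:
    """OLS slope (value per month) of (month, value) points; None if underdetermined."""
    if len(points) < 2:
        return None
    months = np.asarray([m for m, _ in points], dtype=float)
    values = np.asarray([v for _, v in points], dtype=float)
    dm = months - months.mean()
    denom = float(np.dot(dm, dm))
    if denom == 0.0:
        return None
    return float(np.dot(dm, values - values.mean()) / denom)


def _slope_points(participant: ParticipantSeries, measurement: str, up_to_month: float):
    return [
        (v.month, v.measurements[measurement])
        for v in participant.visits
        if v.month <= up_to_month and measurement in v.measurements
    ]


def _source_features(
    participant: ParticipantSeries,
    source: Visit,
    spec: FeatureSpec,
    delta_t: float,
) -> dict[str, float | None]:
    """Assemble the feature map for one source visit and time delay.

    Slope features use only visits at months <= the source month, so no
    information from the destination side of the pair can leak in.
    """
    feats: dict[str, float | None] = {}
    for name in spec.feature_names:
        if name == "TIME_DELAY":
            feats[name] = float(delta_t)
        elif name == "DX":
            dx = source.diagnosis
            feats[name] = DX_CODE[dx] if dx is not None else None
        elif name == "AGE":
            if participant.age_baseline is None:
                feats[name] = None
            else:
                feats[name] = participant.age_baseline + source.month / 12.0
        elif name == "GENDER":
            g = participant.gender
            feats[name] = GENDER_CODE[g] if g is not None else None
        elif name == "APOE":
            feats[name] = float(participant.apoe4) if participant.apoe4 is not None else None
        elif name == "RID":
            feats[name] = float(participant.rid)
        elif name == "MMSE":
            feats[name] = binarize_mmse(source.measurements.get("MMSE"))
        elif name in SLOPE_BASE:
            feats[name] = compute_slope(
                _slope_points(participant, SLOPE_BASE[name], source.month)
            )
        elif name in TIME_VARYING:
            feats[name] = source.measurements.get(name)
        else:
            raise ValueError(f"unknown feature {name!r}")
    return feats


def _target_at(visit: Visit, target: str):
    """(target_dx, target_value, present?) at a destination visit."""
    if target == "DIAGNOSIS":
        return visit.diagnosis, None, visit.diagnosis is not None
    meas = TARGET_MEASUREMENT[target]
    value = visit.measurements.get(meas)
    return None, value, value is not None


def build_pairs(cohort: Cohort, spec: FeatureSpec) -> list[PairSample]:
    """Expand a cohort into all forward visit pairs with the target observed.

    For each participant and each ordered visit pair (i, j) with month_i <
    month_j and the target present at j, emit one sample with features from
    visit i.  Pairs whose DX feature is required but missing at the source
    visit are dropped (the last diagnosis is the model's anchor input).
    """
    needs_dx = "DX" in spec.feature_names
    samples: list[PairSample] = []
    for p in cohort:
        n = len(p.visits)
        for j in range(n):
            dest = p.visits[j]
            target_dx, target_value, present = _target_at(dest, spec.target)
            if not present:
                continue
            for i in range(j):
                src = p.visits[i]
                if needs_dx and src.diagnosis is None:
                    continue
                dt = dest.month - src.month
                samples.append(
                    PairSample(
                        rid=p.rid,
                        source_month=src.month,
                        delta_t=dt,
                        features=_source_features(p, src, spec, dt),
                        target_dx=target_dx,
                        target_value=target_value,
                    )
                )
    return samples


def _select_source(participant: ParticipantSeries, spec: FeatureSpec) -> Visit:
    """Latest visit with all required time-varying features observed.

    Falls back to the latest visit with any of them observed, then to the
    last visit outright (remaining features stay missing for the imputer).
    """
    required = spec.required_time_varying

    def observed(v: Visit, name: str) -> bool:
        if name == "DX":
            return v.diagnosis is not None
        return name in v.measurements

    for v in reversed(participant.visits):
        if all(observed(v, name) for name in required):
            return v
    for v in reversed(participant.visits):
        if any(observed(v, name) for name in required):
            return v
    return participant.last_visit()


def build_forecast_inputs(
    history: Cohort,
    horizons: Mapping[int, Sequence[float]],
    spec: FeatureSpec,
) -> list[PairSample]:
    """Build prediction-time samples (targets missing) for requested months.

    ``horizons`` maps rid -> forecast months (months since that participant's
    baseline).  The source visit is chosen by :func:`_select_source`; the time
    delay is forecast month minus source month and must be positive.
    """
    samples: list[PairSample] = []
    for rid, months in horizons.items():
        try:
            p = history.by_rid(rid)
        except KeyError:
            raise ValueError(f"rid {rid} absent from history cohort") from None
        source = _select_source(p, spec)
        for fm in months:
            dt = float(fm) - source.month
            if dt <= 0:
                raise ValueError(
                    f"rid {rid}: forecast month {fm} is not after source month {source.month}"
                )
            samples.append(
                PairSample(
                    rid=p.rid,
                    source_month=source.month,
                    delta_t=dt,
                    features=_source_features(p, source, spec, dt),
                )
            )
    return samples


def impute_missing(
    samples: Sequence[PairSample],
    reference: Sequence[PairSample],
) -> list[PairSample]:
    """Fill missing feature values from reference statistics.

    Numeric features get the reference median, categorical features (DX,
    GENDER) the reference mode (ties to the smaller code), and slope features
    missing in a sample are set to 0 (no observed trend).  Deterministic.
    """
    if not reference:
        raise ValueError("reference sample list is empty")
    names = list(reference[0].features.keys())

    fills: dict[str, float] = {}
    for name in names:
        if name.startswith(SLOPE_PREFIX):
            fills[name] = 0.0
            continue
        values = [s.features[name] for s in reference if s.features.get(name) is not None]
        if not values:
            raise ValueError(f"feature {name!r} missing in every reference sample")
        if name in CATEGORICAL:
            codes, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
            fills[name] = float(codes[np.argmax(counts)])
        else:
            fills[name] = float(np.median(np.asarray(values, dtype=float)))

    out = []
    for s in samples:
        feats = {
            name: (value if value is not None else fills[name])
            for name, value in s.features.items()
        }
        out.append(replace(copy.copy(s), features=feats))
    return out
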