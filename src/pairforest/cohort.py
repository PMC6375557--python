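"""Data model and file I/O for irregularly sampled longitudinal cohorts.

A cohort is a set of participants, each with static covariates (baseline age,
gender, ApoE4 allele count) and a time-ordered list of visits at irregular
month offsets.  Each visit carries an optional three-state clinical diagnosis
(NL / MCI / AD) and a sparse map of continuous measurements (cognitive scores
and MRI volumes).  Cohorts are read from and written to long-format CSV files
with one row per (participant, month); forecasts are written in the TADPOLE
submission layout (per-class diagnosis probabilities plus point estimates and
50% intervals for ADAS-13 and the ventricles/ICV ratio).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("pairforest")

#: Diagnosis labels, in progression order.
DIAGNOSES = ("NL", "MCI", "AD")

#: Continuous per-visit measurements the model knows about.
MEASUREMENTS = (
    "MMSE",
    "ADAS13",
    "CDRSB",
    "FAQ",
    "VENTRICLES",
    "ICV",
    "MIDTEMP",
    "HIPPOCAMPUS",
)

#: Default column names for the long-format visit CSV.  A user-supplied schema
#: map (logical name -> actual column name) overrides any subset of these.
DEFAULT_SCHEMA = {
    "RID": "RID",
    "MONTH": "MONTH",
    "DX": "DX",
    "AGE": "AGE",
    "GENDER": "GENDER",
    "APOE4": "APOE4",
    "PHASE_BOUNDARY": "PHASE_BOUNDARY",
    **{m: m for m in MEASUREMENTS},
}

FORECAST_HEADER = [
    "RID",
    "Forecast_Month",
    "CN_prob",
    "MCI_prob",
    "AD_prob",
    "ADAS13",
    "ADAS13_CI_lower",
    "ADAS13_CI_upper",
    "Ventricles_ICV",
    "Ventricles_ICV_CI_lower",
    "Ventricles_ICV_CI_upper",
]


@dataclass
class Visit:
    """One clinical visit: months since baseline, diagnosis, measurements."""

    month: float
    diagnosis: str | None = None
    measurements: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not math.isfinite(self.month) or self.month < 0:
            raise ValueError(f"visit month must be finite and >= 0, got {self.month}")
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        for name, value in self.measurements.items():
            if value is None:
                raise ValueError(f"measurement {name} is None; omit missing values")
            if not math.isfinite(value):
                raise ValueError(f"measurement {name} is not finite: {value}")
        mmse = self.measurements.get("MMSE")
        if mmse is not None and not 0 <= mmse <= 30:
            raise ValueError(f"MMSE out of range [0, 30]: {mmse}")


@dataclass
class ParticipantSeries:
    """A participant's static covariates and time-ordered visit series.

    ``phase_boundary`` marks the last month belonging to the "history" phase
    (the analogue of the end of ADNI-1); visits at months <= boundary form the
    history-phase sub-series used by the matching procedure.
    """

    rid: int
    age_baseline: float | None = None
    gender: str | None = None  # "male" | "female"
    apoe4: int | None = None
    visits: list[Visit] = field(default_factory=list)
    phase_boundary: float | None = None

    def validate(self) -> None:
        if self.apoe4 is not None and self.apoe4 not in (0, 1, 2):
            raise ValueError(f"rid {self.rid}: apoe4 must be 0, 1 or 2, got {self.apoe4}")
        if self.gender is not None and self.gender not in ("male", "female"):
            raise ValueError(f"rid {self.rid}: unknown gender {self.gender!r}")
        months = [v.month for v in self.visits]
        for a, b in zip(months, months[1:]):
            if not a < b:
                raise ValueError(f"rid {self.rid}: visit months not strictly increasing")
        for v in self.visits:
            v.validate()

    def history_visits(self) -> list[Visit]:
        """Visits within the history phase (all visits if no boundary set)."""
        if self.phase_boundary is None:
            return list(self.visits)
        return [v for v in self.visits if v.month <= self.phase_boundary]

    def last_visit(self) -> Visit:
        if not self.visits:
            raise ValueError(f"rid {self.rid}: no visits")
        return self.visits[-1]


@dataclass
class Cohort:
    """A named collection of participants with unique RIDs."""

    participants: list[ParticipantSeries] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        rids = [p.rid for p in self.participants]
        if len(rids) != len(set(rids)):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ValueError(f"duplicate rid(s) in cohort: {dupes}")

    def __iter__(self) -> Iterator[ParticipantSeries]:
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)

    def by_rid(self, rid: int) -> ParticipantSeries:
        for p in self.participants:
            if p.rid == rid:
                return p
        raise KeyError(f"rid {rid} not in cohort {self.name!r}")

    @property
    def rids(self) -> list[int]:
        return [p.rid for p in self.participants]


@dataclass
class ForecastRow:
    """One forecast: per-class diagnosis probabilities and interval estimates."""

    rid: int
    forecast_month: float
    p_nl: float
    p_mci: float
    p_ad: float
    adas13: float
    adas13_lo: float
    adas13_hi: float
    vents_icv: float
    vents_icv_lo: float
    vents_icv_hi: float

    def validate(self) -> None:
        probs = (self.p_nl, self.p_mci, self.p_ad)
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(
                f"rid {self.rid} month {self.forecast_month}: "
                f"diagnosis probabilities sum to {sum(probs)}, not 1"
            )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rid {self.rid}: probability {p} outside [0, 1]")
        if not self.adas13_lo <= self.adas13 <= self.adas13_hi:
            raise ValueError(f"rid {self.rid}: ADAS13 point outside its interval")
        if not self.vents_icv_lo <= self.vents_icv <= self.vents_icv_hi:
            raise ValueError(f"rid {self.rid}: Ventricles_ICV point outside its interval")


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------


def _parse_diagnosis(raw: object, row_index: int) -> str | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    if text in DIAGNOSES:
        return text
    raise ValueError(f"row {row_index}: unknown diagnosis string {text!r}")


def _parse_gender(raw: object) -> str | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip().lower()
    if text == "":
        return None
    if text in ("male", "m", "1"):
        return "male"
    if text in ("female", "f", "0"):
        return "female"
    raise ValueError(f"unknown gender string {raw!r}")


def _numeric_column(frame: pd.DataFrame, column: str) -> pd.Series:
    """Coerce a column to float, reporting the first offending row index."""
    raw = frame[column]
    coerced = pd.to_numeric(raw, errors="coerce")
    blank = raw.isna() | (raw.astype(str).str.strip() == "")
    bad = coerced.isna() & ~blank
    if bad.any():
        idx = int(bad.idxmax())
        raise ValueError(f"row {idx}: non-numeric value {raw[idx]!r} in column {column}")
    return coerced


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    name: str = "",
) -> Cohort:
    """Read a long-format visit CSV into a :class:`Cohort`.

    One row per (RID, MONTH); empty cells denote missing values.  Rows are
    grouped by RID and sorted by month.  Static covariates are taken from the
    earliest row with a non-missing value; conflicting later values trigger a
    warning and are ignored.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)

    rid_col, month_col = cols["RID"], cols["MONTH"]
    for required in (rid_col, month_col):
        if required not in frame.columns:
            raise ValueError(f"missing required column {required!r} in {path}")

    rid_series = _numeric_column(frame, rid_col)
    month_series = _numeric_column(frame, month_col)
    if rid_series.isna().any() or month_series.isna().any():
        idx = int((rid_series.isna() | month_series.isna()).idxmax())
        raise ValueError(f"row {idx}: missing RID or MONTH")

    dup = pd.DataFrame({"rid": rid_series, "month": month_series}).duplicated(keep=False)
    if dup.any():
        rid = int(rid_series[dup.idxmax()])
        raise ValueError(f"duplicate (rid, month) rows for rid {rid}")

    numeric_logical = ["AGE", "APOE4", *MEASUREMENTS, "PHASE_BOUNDARY"]
    numeric: dict[str, pd.Series] = {}
    for logical in numeric_logical:
        col = cols[logical]
        if col in frame.columns:
            numeric[logical] = _numeric_column(frame, col)

    participants = []
    order = sorted(range(len(frame)), key=lambda i: (rid_series[i], month_series[i]))
    by_rid: dict[int, list[int]] = {}
    for i in order:
        by_rid.setdefault(int(rid_series[i]), []).append(i)

    dx_col = cols["DX"]
    gender_col = cols["GENDER"]
    for rid, rows in by_rid.items():
        visits = []
        age = apoe = boundary = gender = None
        for i in rows:
            dx = _parse_diagnosis(frame[dx_col][i], i) if dx_col in frame.columns else None
            meas = {}
            for m in MEASUREMENTS:
                if m in numeric and not pd.isna(numeric[m][i]):
                    meas[m] = float(numeric[m][i])
            visits.append(Visit(month=float(month_series[i]), diagnosis=dx, measurements=meas))

            if "AGE" in numeric and not pd.isna(numeric["AGE"][i]):
                value = float(numeric["AGE"][i])
                if age is None:
                    age = value
                elif value != age:
                    logger.warning("rid %s: conflicting AGE %s, keeping first %s", rid, value, age)
            if "APOE4" in numeric and not pd.isna(numeric["APOE4"][i]):
                value = int(numeric["APOE4"][i])
                if apoe is None:
                    apoe = value
                elif value != apoe:
                    logger.warning("rid %s: conflicting APOE4 %s, keeping first %s", rid, value, apoe)
            if "PHASE_BOUNDARY" in numeric and not pd.isna(numeric["PHASE_BOUNDARY"][i]):
                value = float(numeric["PHASE_BOUNDARY"][i])
                if boundary is None:
                    boundary = value
            if gender_col in frame.columns:
                g = _parse_gender(frame[gender_col][i])
                if g is not None:
                    if gender is None:
                        gender = g
                    elif g != gender:
                        logger.warning("rid %s: conflicting gender %s, keeping first %s", rid, g, gender)

        series = ParticipantSeries(
            rid=rid,
            age_baseline=age,
            gender=gender,
            apoe4=apoe,
            visits=visits,
            phase_boundary=boundary,
        )
        series.validate()
        participants.append(series)

    return Cohort(participants=participants, name=name or Path(path).stem)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the long-format visit CSV (inverse of read_cohort)."""
    records = []
    for p in cohort:
        for v in p.visits:
            rec: dict[str, object] = {
                "RID": p.rid,
                "MONTH": v.month,
                "DX": v.diagnosis if v.diagnosis is not None else "",
                "AGE": p.age_baseline if p.age_baseline is not None else "",
                "GENDER": p.gender if p.gender is not None else "",
                "APOE4": p.apoe4 if p.apoe4 is not None else "",
                "PHASE_BOUNDARY": p.phase_boundary if p.phase_boundary is not None else "",
            }
            for m in MEASUREMENTS:
                rec[m] = v.measurements.get(m, "")
            records.append(rec)
    columns = ["RID", "MONTH", "DX", "AGE", "GENDER", "APOE4", "PHASE_BOUNDARY", *MEASUREMENTS]
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Forecast CSV I/O
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Serialize with >= 6 significant digits (round-trips to 1e-6)."""
    return format(float(x), ".10g")


def write_forecasts(rows: Sequence[ForecastRow], path: str | Path) -> None:
    """Write forecast rows in the submission CSV layout.

    All rows are validated before anything is written, so an invalid row never
    leaves a partial file behind.
    """
    for row in rows:
        row.validate()
    lines = [",".join(FORECAST_HEADER)]
    for r in rows:
        lines.append(
            ",".join(
                [
                    str(int(r.rid)),
                    _fmt(r.forecast_month),
                    _fmt(r.p_nl),
                    _fmt(r.p_mci),
                    _fmt(r.p_ad),
                    _fmt(r.adas13),
                    _fmt(r.adas13_lo),
                    _fmt(r.adas13_hi),
                    _fmt(r.vents_icv),
                    _fmt(r.vents_icv_lo),
                    _fmt(r.vents_icv_hi),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_forecasts(path: str | Path) -> list[ForecastRow]:
    frame = pd.read_csv(path)
    missing = [c for c in FORECAST_HEADER if c not in frame.columns]
    if missing:
        raise ValueError(f"forecast CSV missing columns: {missing}")
    rows = []
    for rec in frame.itertuples(index=False):
        row = ForecastRow(
            rid=int(rec.RID),
            forecast_month=float(rec.Forecast_Month),
            p_nl=float(rec.CN_prob),
            p_mci=float(rec.MCI_prob),
            p_ad=float(rec.AD_prob),
            adas13=float(rec.ADAS13),
            adas13_lo=float(rec.ADAS13_CI_lower),
            adas13_hi=float(rec.ADAS13_CI_upper),
            vents_icv=float(rec.Ventricles_ICV),
            vents_icv_lo=float(rec.Ventricles_ICV_CI_lower),
            vents_icv_hi=float(rec.Ventricles_ICV_CI_upper),
        )
        row.validate()
        rows.append(row)
    return rows
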