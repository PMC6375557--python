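"""TADPOLE-style forecast evaluation metrics.

Diagnosis forecasts (probability triples over NL / MCI / AD) are scored with
the Hand–Till multiclass AUC (mAUC) and balanced classification accuracy
(BCA); continuous forecasts with the mean absolute error (MAE); submitted 50%
intervals with the weighted error score (WES, absolute error weighted by
inverse interval width) and the coverage probability accuracy
(CPA = |j - 0.5|, j the fraction of truths falling inside the interval).

Hand & Till's mAUC: for an ordered class pair (i, j), rank the n_i + n_j
samples of the two classes by the probability assigned to class i and let S_i
be the sum of midranks of the class-i samples; then
``A(i|j) = (S_i - n_i(n_i+1)/2) / (n_i n_j)``, the pairwise score is the
average of A(i|j) and A(j|i), and mAUC averages over the unordered class
pairs.  Midranks make chance-level (all-tied) input score exactly 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .cohort import DIAGNOSES, Cohort, ForecastRow

DX_INDEX = {d: i for i, d in enumerate(DIAGNOSES)}


@dataclass
class ConfusionMatrix:
    """3x3 counts of actual (rows) vs predicted (columns) diagnosis."""

    counts: np.ndarray  # (3, 3) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.diag(self.counts) / totals
        return acc

    @property
    def overall_accuracy(self) -> float:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts) / total)


@dataclass
class MetricsReport:
    mauc: float | None = None
    bca: float | None = None
    mae_adas13: float | None = None
    mae_vents_icv: float | None = None
    wes_adas13: float | None = None
    wes_vents_icv: float | None = None
    cpa_adas13: float | None = None
    cpa_vents_icv: float | None = None
    n_dx_points: int = 0
    n_adas13_points: int = 0
    n_vents_icv_points: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _as_indices(labels: Sequence[str | int]) -> np.ndarray:
    out = np.empty(len(labels), dtype=int)
    for k, lab in enumerate(labels):
        out[k] = DX_INDEX[lab] if isinstance(lab, str) else int(lab)
    if len(out) and not ((out >= 0) & (out < 3)).all():
        raise ValueError("labels must be NL/MCI/AD or indices 0..2")
    return out


def _auc_one_vs_one(prob_i: np.ndarray, is_i: np.ndarray) -> float:
    """A(i|j) on the restricted two-class sample via the midrank formula."""
    n_i = int(is_i.sum())
    n_j = int((~is_i).sum())
    ranks = rankdata(prob_i)  # midranks for ties
    s_i = float(ranks[is_i].sum())
    return (s_i - n_i * (n_i + 1) / 2.0) / (n_i * n_j)


def hand_till_mauc(labels: Sequence[str | int], probs: np.ndarray) -> float:
    """Hand–Till multiclass AUC over the three diagnosis classes.

    Class pairs where one class has no samples are skipped; if every pair is
    skipped (fewer than two classes present) this is an error.
    """
    y = _as_indices(labels)
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2 or p.shape != (len(y), 3):
        raise ValueError("probs must be (n_samples, 3)")
    pair_scores = []
    for i in range(3):
        for j in range(i + 1, 3):
            mask = (y == i) | (y == j)
            if not (y == i).any() or not (y == j).any():
                continue
            is_i = y[mask] == i
            a_ij = _auc_one_vs_one(p[mask, i], is_i)
            a_ji = _auc_one_vs_one(p[mask, j], ~is_i)
            pair_scores.append(0.5 * (a_ij + a_ji))
    if not pair_scores:
        raise ValueError("need at least two classes present to compute mAUC")
    return float(np.mean(pair_scores))


def argmax_labels(probs: np.ndarray) -> np.ndarray:
    """Hard labels from probability triples; ties go to the lower class index."""
    p = np.asarray(probs, dtype=float)
    return p.argmax(axis=1)  # np.argmax returns the first (lowest) max index


def bca(labels: Sequence[str | int], predicted: Sequence[str | int]) -> float:
    """Balanced classification accuracy, averaged one-vs-rest over classes.

    Classes absent from the true labels are excluded; within an included
    class, an undefined ratio (0/0) is skipped and the defined one used.
    """
    y = _as_indices(labels)
    yhat = _as_indices(predicted)
    if len(y) == 0 or len(y) != len(yhat):
        raise ValueError("labels and predictions must be non-empty, equal length")
    scores = []
    for c in range(3):
        if not (y == c).any():
            continue
        tp = int(((y == c) & (yhat == c)).sum())
        fn = int(((y == c) & (yhat != c)).sum())
        tn = int(((y != c) & (yhat != c)).sum())
        fp = int(((y != c) & (yhat == c)).sum())
        parts = []
        if tp + fn > 0:
            parts.append(tp / (tp + fn))
        if tn + fp > 0:
            parts.append(tn / (tn + fp))
        if parts:
            scores.append(float(np.mean(parts)))
    if not scores:
        raise ValueError("BCA undefined: no class has any defined ratio")
    return float(np.mean(scores))


def confusion(labels: Sequence[str | int], predicted: Sequence[str | int]) -> ConfusionMatrix:
    y = _as_indices(labels)
    yhat = _as_indices(predicted)
    if len(y) == 0 or len(y) != len(yhat):
        raise ValueError("labels and predictions must be non-empty, equal length")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (y, yhat), 1)
    return ConfusionMatrix(counts=counts)


def mae(truth: Sequence[float], estimates: Sequence[float]) -> float:
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.size == 0 or t.shape != e.shape:
        raise ValueError("truth and estimates must be non-empty, equal length")
    return float(np.abs(t - e).mean())


def wes(
    truth: Sequence[float],
    estimates: Sequence[float],
    intervals: Sequence[tuple[float, float]],
) -> float:
    """Weighted error score: |error| weighted by 1/interval width, normalized.

    Zero-width (degenerate) intervals get weight 1/eps with eps equal to 1e-6
    of the truth standard deviation, so overconfident point intervals dominate
    the score instead of dividing by zero.
    """
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimates, dtype=float)
    iv = np.asarray(intervals, dtype=float)
    if t.size == 0 or iv.shape != (t.size, 2) or t.shape != e.shape:
        raise ValueError("inconsistent input lengths")
    widths = iv[:, 1] - iv[:, 0]
    if (widths < 0).any():
        raise ValueError("interval upper bound below lower bound")
    errors = np.abs(t - e)
    if (widths == 0).all() and (errors == 0).all():
        return 0.0
    eps = 1e-6 * float(t.std())
    if eps == 0.0:
        eps = 1e-6
    weights = 1.0 / np.where(widths > 0, widths, eps)
    return float(np.sum(weights * errors) / np.sum(weights))


def cpa(truth: Sequence[float], intervals: Sequence[tuple[float, float]]) -> float:
    """Coverage probability accuracy |j - 0.5|; boundaries count as inside."""
    t = np.asarray(truth, dtype=float)
    iv = np.asarray(intervals, dtype=float)
    if t.size == 0 or iv.shape != (t.size, 2):
        raise ValueError("inconsistent input lengths")
    inside = (iv[:, 0] <= t) & (t <= iv[:, 1])
    return float(abs(inside.mean() - 0.5))


# ---------------------------------------------------------------------------
# Forecast-vs-truth evaluation with month matching
# ---------------------------------------------------------------------------


def _match_row(rows: list[ForecastRow], month: float, tolerance: float) -> ForecastRow | None:
    best = None
    best_key = None
    for r in rows:
        gap = abs(r.forecast_month - month)
        if gap <= tolerance:
            key = (gap, r.forecast_month)
            if best_key is None or key < best_key:
                best, best_key = r, key
    return best


def evaluate_forecasts(
    forecasts: Sequence[ForecastRow],
    truth: Cohort,
    tolerance: float = 3.0,
) -> tuple[MetricsReport, ConfusionMatrix | None]:
    """Score forecast rows against observed truth visits.

    Each truth visit is matched to the forecast row of the same participant
    whose forecast month is nearest within ``tolerance`` months (ties to the
    earlier forecast month).  Diagnosis points need an observed diagnosis;
    ADAS-13 points an observed ADAS13; ventricle-ratio points both VENTRICLES
    and ICV.  Raises if no truth point matches any forecast.
    """
    by_rid: dict[int, list[ForecastRow]] = {}
    for r in forecasts:
        by_rid.setdefault(r.rid, []).append(r)

    dx_true: list[int] = []
    dx_probs: list[list[float]] = []
    adas_t: list[float] = []
    adas_e: list[float] = []
    adas_iv: list[tuple[float, float]] = []
    vi_t: list[float] = []
    vi_e: list[float] = []
    vi_iv: list[tuple[float, float]] = []

    for p in truth:
        rows = by_rid.get(p.rid)
        if not rows:
            continue
        for v in p.visits:
            row = _match_row(rows, v.month, tolerance)
            if row is None:
                continue
            if v.diagnosis is not None:
                dx_true.append(DX_INDEX[v.diagnosis])
                dx_probs.append([row.p_nl, row.p_mci, row.p_ad])
            if "ADAS13" in v.measurements:
                adas_t.append(v.measurements["ADAS13"])
                adas_e.append(row.adas13)
                adas_iv.append((row.adas13_lo, row.adas13_hi))
            if "VENTRICLES" in v.measurements and "ICV" in v.measurements:
                icv = v.measurements["ICV"]
                if icv > 0:
                    vi_t.append(v.measurements["VENTRICLES"] / icv)
                    vi_e.append(row.vents_icv)
                    vi_iv.append((row.vents_icv_lo, row.vents_icv_hi))

    if not dx_true and not adas_t and not vi_t:
        raise ValueError("no truth points matched any forecast row")

    report = MetricsReport(
        n_dx_points=len(dx_true),
        n_adas13_points=len(adas_t),
        n_vents_icv_points=len(vi_t),
    )
    cm = None
    if dx_true:
        probs = np.asarray(dx_probs, dtype=float)
        if len(set(dx_true)) >= 2:
            report.mauc = hand_till_mauc(dx_true, probs)
        predicted = argmax_labels(probs)
        report.bca = bca(dx_true, predicted)
        cm = confusion(dx_true, predicted)
    if adas_t:
        report.mae_adas13 = mae(adas_t, adas_e)
        report.wes_adas13 = wes(adas_t, adas_e, adas_iv)
        report.cpa_adas13 = cpa(adas_t, adas_iv)
    if vi_t:
        report.mae_vents_icv = mae(vi_t, vi_e)
        report.wes_vents_icv = wes(vi_t, vi_e, vi_iv)
        report.cpa_vents_icv = cpa(vi_t, vi_iv)
    return report, cm
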