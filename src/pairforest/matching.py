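"""Matched evaluation-set construction.

For each participant in the history cohort (the LB2 analogue: series truncated
at the history-phase boundary), find a training-cohort participant with the
same gender and ApoE4 allele count, baseline age within 5 years, and the same
diagnosis at the first and last history-phase visit; among candidates, pick
the one whose history-phase series length is closest.  Matching is greedy in
ascending history RID and without replacement, so the result is deterministic
and each training participant backs at most one evaluation participant.  The
matched set stands in for the held-out group during training-time validation:
its post-boundary visits resemble what the real test set will look like.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort, ParticipantSeries


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]] = field(default_factory=list)
    unmatched: list[int] = field(default_factory=list)

    @property
    def matched_train_rids(self) -> list[int]:
        return [t for _, t in self.pairs]


def _phase_dx_endpoints(p: ParticipantSeries) -> tuple[str | None, str | None]:
    """First and last non-missing diagnosis within the history phase."""
    dxs = [v.diagnosis for v in p.history_visits() if v.diagnosis is not None]
    if not dxs:
        return None, None
    return dxs[0], dxs[-1]


def _phase_length(p: ParticipantSeries) -> int:
    return len(p.history_visits())


def match_evaluation_set(train: Cohort, history: Cohort) -> MatchResult:
    """Greedy without-replacement attribute matching, ascending history rid.

    Hard criteria: equal gender, equal ApoE4 count, |baseline age difference|
    <= 5 years, equal diagnosis at both history-phase endpoints.  Among
    candidates the smallest history-phase visit-count difference wins, ties
    broken by the lowest candidate rid.
    """
    result = MatchResult()
    used: set[int] = set()
    train_sorted = sorted(train.participants, key=lambda p: p.rid)

    for target in sorted(history.participants, key=lambda p: p.rid):
        t_first, t_last = _phase_dx_endpoints(target)
        t_len = _phase_length(target)
        best: ParticipantSeries | None = None
        best_key: tuple[int, int] | None = None
        for cand in train_sorted:
            if cand.rid in used:
                continue
            if cand.gender is None or cand.gender != target.gender:
                continue
            if cand.apoe4 is None or cand.apoe4 != target.apoe4:
                continue
            if cand.age_baseline is None or target.age_baseline is None:
                continue
            if abs(cand.age_baseline - target.age_baseline) > 5.0:
                continue
            c_first, c_last = _phase_dx_endpoints(cand)
            if c_first is None or c_first != t_first or c_last != t_last:
                continue
            key = (abs(_phase_length(cand) - t_len), cand.rid)
            if best_key is None or key < best_key:
                best, best_key = cand, key
        if best is None:
            result.unmatched.append(target.rid)
        else:
            used.add(best.rid)
            result.pairs.append((target.rid, best.rid))
    return result


def cohort_summary(cohort: Cohort) -> dict[str, float]:
    """Demographic summary: n, age min/mean/max, % gender, % ApoE4 counts."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    ages = np.asarray(
        [p.age_baseline for p in cohort if p.age_baseline is not None], dtype=float
    )
    genders = [p.gender for p in cohort if p.gender is not None]
    apoes = [p.apoe4 for p in cohort if p.apoe4 is not None]
    summary: dict[str, float] = {"n": float(len(cohort))}
    if ages.size:
        summary["age_min"] = float(ages.min())
        summary["age_mean"] = float(ages.mean())
        summary["age_max"] = float(ages.max())
    if genders:
        summary["pct_male"] = 100.0 * sum(g == "male" for g in genders) / len(genders)
        summary["pct_female"] = 100.0 - summary["pct_male"]
    if apoes:
        for k in (0, 1, 2):
            summary[f"pct_apoe4_{k}"] = 100.0 * sum(a == k for a in apoes) / len(apoes)
    return summary


def write_match_result(result: MatchResult, path: str | Path) -> None:
    """Two-column CSV (history_rid, train_rid); unmatched rows leave train_rid blank."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["history_rid", "train_rid"])
        for h, t in result.pairs:
            writer.writerow([h, t])
        for h in result.unmatched:
            writer.writerow([h, ""])
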