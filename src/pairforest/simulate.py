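"""Synthetic ADNI-like cohort generation with known ground truth.

Disease progression is a forward-only three-state continuous-time Markov
chain NL -> MCI -> AD with exponential sojourn times.  Per-participant
transition intensities are the base rates scaled multiplicatively per ApoE4
allele and per decade of baseline age above the cohort mean.  Demographics
follow the target cohort's composition: mean age 75 (SD 6, clipped to
[55, 90]), 60.9% male, ApoE4 allele counts with probabilities
0.70 / 0.27 / 0.03.  Visits follow the ADNI-style nominal schedule (months 0,
6, 12, 18, 24, 36, 48, ...) with uniform +/-2-month jitter and permanent
dropout, giving the right-skewed series-length distribution seen in such
cohorts.  Each biomarker is a per-participant Gaussian baseline plus a
state-dependent offset, a state-dependent drift integrated over the time
spent in each state, and Gaussian measurement noise; observations go missing
completely at random per variable.

The simulator also performs the leaderboard-style split: a small fraction of
participants contribute their visits up to the history-phase boundary to a
"history" cohort and their later visits to a "test" cohort (participants
already diagnosed AD at their last history-phase visit are ineligible, as in
the leaderboard construction); everyone else goes wholesale to "train".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import Cohort, ParticipantSeries, Visit

STATE_NAMES = ("NL", "MCI", "AD")


@dataclass(frozen=True)
class BiomarkerModel:
    """Gaussian baseline + state offset + state-drift integral + noise."""

    mean: float
    sd: float
    state_offset: tuple[float, float, float]  # added once, by baseline state
    drift: tuple[float, float, float]  # units per month while in each state
    noise_sd: float
    p_missing: float
    lo: float | None = None
    hi: float | None = None


def _default_biomarkers() -> dict[str, BiomarkerModel]:
    return {
        "MMSE": BiomarkerModel(29.0, 1.0, (0.0, -2.5, -7.0), (-0.005, -0.04, -0.20), 0.8, 0.05, 0.0, 30.0),
        "ADAS13": BiomarkerModel(9.0, 3.5, (0.0, 6.0, 18.0), (0.01, 0.08, 0.35), 2.0, 0.10, 0.0, 85.0),
        "CDRSB": BiomarkerModel(0.3, 0.4, (0.0, 1.3, 4.0), (0.0, 0.03, 0.15), 0.4, 0.10, 0.0, 18.0),
        "FAQ": BiomarkerModel(0.5, 1.0, (0.0, 2.5, 10.0), (0.0, 0.05, 0.25), 1.0, 0.10, 0.0, 30.0),
        "VENTRICLES": BiomarkerModel(30000.0, 11000.0, (0.0, 4000.0, 9000.0), (20.0, 45.0, 90.0), 800.0, 0.15, 1000.0, None),
        "ICV": BiomarkerModel(1.5e6, 1.5e5, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), 5000.0, 0.15, 1e5, None),
        "MIDTEMP": BiomarkerModel(20000.0, 2200.0, (0.0, -1200.0, -3000.0), (-2.0, -12.0, -30.0), 300.0, 0.15, 1000.0, None),
        "HIPPOCAMPUS": BiomarkerModel(7000.0, 900.0, (0.0, -600.0, -1400.0), (-1.0, -5.0, -12.0), 120.0, 0.15, 500.0, None),
    }


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one synthetic cohort."""

    n_participants: int = 500
    seed: int = 0
    # demographics
    age_mean: float = 75.0
    age_sd: float = 6.0
    age_clip: tuple[float, float] = (55.0, 90.0)
    p_male: float = 0.609
    apoe4_probs: tuple[float, float, float] = (0.70, 0.27, 0.03)
    # baseline diagnosis mixture (NL, MCI); remainder starts as AD
    baseline_dx_probs: tuple[float, float] = (0.25, 0.50)
    # progression intensities (per month) and multiplicative risk modifiers
    lam_nl_mci: float = 0.004
    lam_mci_ad: float = 0.008
    apoe4_modifier: float = 1.5  # per allele
    age_modifier_per_decade: float = 1.2  # per decade above age_mean
    # visit process
    nominal_months: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0)
    visit_jitter: float = 2.0
    p_dropout: float = 0.15  # per scheduled visit after baseline, permanent
    p_missing_dx: float = 0.03
    # biomarker models
    biomarkers: dict[str, BiomarkerModel] = field(default_factory=_default_biomarkers)
    # leaderboard-style split
    phase_boundary_month: float = 36.0
    history_fraction: float = 110.0 / 1737.0

    def __post_init__(self) -> None:
        for p in (self.p_male, self.p_dropout, self.p_missing_dx, *self.apoe4_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.apoe4_probs) - 1.0) > 1e-9:
            raise ValueError("apoe4_probs must sum to 1")
        if self.lam_nl_mci < 0 or self.lam_mci_ad < 0:
            raise ValueError("transition intensities must be >= 0")


@dataclass
class GroundTruth:
    """True transition months and noiseless biomarker values per participant.

    ``transitions[rid] = (t_mci, t_ad)`` in months since baseline; 0.0 means
    the state was reached at or before baseline, ``inf`` never.  ``noiseless``
    maps rid -> {"months": [...], variable: [...]} aligned with the visits.
    """

    transitions: dict[int, tuple[float, float]] = field(default_factory=dict)
    noiseless: dict[int, dict[str, list[float]]] = field(default_factory=dict)

    def state_at(self, rid: int, month: float) -> str:
        t_mci, t_ad = self.transitions[rid]
        if month >= t_ad:
            return "AD"
        if month >= t_mci:
            return "MCI"
        return "NL"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "transitions": {
                str(rid): [t if np.isfinite(t) else None for t in ts]
                for rid, ts in self.transitions.items()
            },
            "noiseless": {str(rid): vals for rid, vals in self.noiseless.items()},
        }
        Path(path).write_text(json.dumps(payload))


def _draw_transitions(rng: np.random.Generator, state0: int, lam1: float, lam2: float):
    """(t_mci, t_ad) for one participant given its baseline state and rates."""
    inf = float("inf")
    if state0 == 2:
        return 0.0, 0.0
    if state0 == 1:
        t_mci = 0.0
    else:
        t_mci = rng.exponential(1.0 / lam1) if lam1 > 0 else inf
    if np.isfinite(t_mci):
        t_ad = t_mci + (rng.exponential(1.0 / lam2) if lam2 > 0 else inf)
    else:
        t_ad = inf
    return float(t_mci), float(t_ad)


def _occupancy(t_mci: float, t_ad: float, month: float) -> tuple[float, float, float]:
    """Months spent in each state on [0, month]."""
    in_nl = min(month, max(t_mci, 0.0))
    in_mci = min(month, max(t_ad, 0.0)) - in_nl
    in_ad = month - in_nl - in_mci
    return in_nl, max(in_mci, 0.0), max(in_ad, 0.0)


def simulate(params: SimParams) -> tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    truth = GroundTruth()
    participants = []
    p_nl, p_mci = params.baseline_dx_probs
    for rid in range(1, params.n_participants + 1):
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), *params.age_clip))
        gender = "male" if rng.random() < params.p_male else "female"
        apoe4 = int(rng.choice(3, p=params.apoe4_probs))
        u = rng.random()
        state0 = 0 if u < p_nl else (1 if u < p_nl + p_mci else 2)

        modifier = (params.apoe4_modifier ** apoe4) * (
            params.age_modifier_per_decade ** ((age - params.age_mean) / 10.0)
        )
        t_mci, t_ad = _draw_transitions(
            rng, state0, params.lam_nl_mci * modifier, params.lam_mci_ad * modifier
        )
        truth.transitions[rid] = (t_mci, t_ad)

        # visit months: baseline always observed, then jittered nominal
        # months until permanent dropout
        months = [0.0]
        for nominal in params.nominal_months[1:]:
            if rng.random() < params.p_dropout:
                break
            months.append(float(nominal + rng.uniform(-params.visit_jitter, params.visit_jitter)))

        baselines = {
            name: rng.normal(bm.mean, bm.sd) + bm.state_offset[state0]
            for name, bm in params.biomarkers.items()
        }

        visits = []
        clean: dict[str, list[float]] = {"months": []}
        for m in months:
            state = 2 if m >= t_ad else (1 if m >= t_mci else 0)
            dx = None if rng.random() < params.p_missing_dx else STATE_NAMES[state]
            occ = _occupancy(t_mci, t_ad, m)
            meas = {}
            clean["months"].append(m)
            for name, bm in params.biomarkers.items():
                value = baselines[name] + float(np.dot(occ, bm.drift))
                if bm.lo is not None:
                    value = max(value, bm.lo)
                if bm.hi is not None:
                    value = min(value, bm.hi)
                clean.setdefault(name, []).append(value)
                if rng.random() < bm.p_missing:
                    continue
                observed = value + rng.normal(0.0, bm.noise_sd)
                if bm.lo is not None:
                    observed = max(observed, bm.lo)
                if bm.hi is not None:
                    observed = min(observed, bm.hi)
                meas[name] = float(observed)
            visits.append(Visit(month=m, diagnosis=dx, measurements=meas))
        truth.noiseless[rid] = clean

        participants.append(
            ParticipantSeries(
                rid=rid,
                age_baseline=age,
                gender=gender,
                apoe4=apoe4,
                visits=visits,
            )
        )
    return Cohort(participants=participants, name="synthetic"), truth


def split_lb(cohort: Cohort, params: SimParams) -> tuple[Cohort, Cohort, Cohort]:
    """Leaderboard-style (train, history, test) split.

    Eligible history/test participants have visits on both sides of the
    phase boundary and are not diagnosed AD at their last history-phase
    visit; a seeded draw selects ``history_fraction`` of the cohort from
    the eligible pool.  All participants carry the phase boundary so the
    matching procedure can reconstruct history-phase sub-series.
    """
    boundary = params.phase_boundary_month

    def last_phase_dx(p: ParticipantSeries) -> str | None:
        dxs = [v.diagnosis for v in p.visits if v.month <= boundary and v.diagnosis is not None]
        return dxs[-1] if dxs else None

    eligible = []
    for p in cohort:
        pre = [v for v in p.visits if v.month <= boundary]
        post = [v for v in p.visits if v.month > boundary]
        dx = last_phase_dx(p)
        if pre and post and dx is not None and dx != "AD":
            eligible.append(p.rid)
    if not eligible:
        raise ValueError("no participant is eligible for the history/test split")

    n_history = max(1, round(params.history_fraction * len(cohort)))
    n_history = min(n_history, len(eligible))
    rng = np.random.default_rng(params.seed + 104729)
    chosen = set(int(r) for r in rng.choice(eligible, size=n_history, replace=False))

    train_p, hist_p, test_p = [], [], []
    for p in cohort:
        if p.rid in chosen:
            pre = [v for v in p.visits if v.month <= boundary]
            post = [v for v in p.visits if v.month > boundary]
            hist_p.append(
                ParticipantSeries(p.rid, p.age_baseline, p.gender, p.apoe4, pre, boundary)
            )
            test_p.append(
                ParticipantSeries(p.rid, p.age_baseline, p.gender, p.apoe4, post, boundary)
            )
        else:
            train_p.append(
                ParticipantSeries(p.rid, p.age_baseline, p.gender, p.apoe4, list(p.visits), boundary)
            )
    return (
        Cohort(train_p, name="train"),
        Cohort(hist_p, name="history"),
        Cohort(test_p, name="test"),
    )
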