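import numpy as np
import pytest

from pairforest.cohort import Cohort, ParticipantSeries, Visit
from pairforest.simulate import SimParams, simulate, split_lb


def make_participant(
    rid,
    months,
    dxs=None,
    age=75.0,
    gender="male",
    apoe4=0,
    phase_boundary=None,
    **measurements,
):
    """Build a participant from parallel per-visit lists.

    Keyword measurement arrays may contain None for missing values.
    """
    n = len(months)
    dxs = dxs if dxs is not None else [None] * n
    visits = []
    for i in range(n):
        meas = {
            name: float(vals[i])
            for name, vals in measurements.items()
            if vals[i] is not None
        }
        visits.append(Visit(month=float(months[i]), diagnosis=dxs[i], measurements=meas))
    return ParticipantSeries(
        rid=rid,
        age_baseline=age,
        gender=gender,
        apoe4=apoe4,
        visits=visits,
        phase_boundary=phase_boundary,
    )


def make_cohort(*participants, name="test"):
    return Cohort(participants=list(participants), name=name)


@pytest.fixture(scope="session")
def sim_default():
    """One moderate synthetic cohort with default progression dynamics."""
    params = SimParams(n_participants=300, seed=7)
    cohort, truth = simulate(params)
    return params, cohort, truth


@pytest.fixture(scope="session")
def sim_split(sim_default):
    params, cohort, _ = sim_default
    return split_lb(cohort, params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
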