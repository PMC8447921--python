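import numpy as np
import pytest

from ardsight.features import NormalizationStats
from ardsight.labels import Encounter, Event, Observation
from ardsight.synth_cohort import CohortConfig, generate_cohort


def make_encounter(
    patient_id="P0",
    spo2=(),
    observations=(),
    events=(),
    discharge=100.0,
    age=60.0,
    sex="female",
    hospital="H0",
):
    """Terse encounter builder: spo2 as (time, value) pairs."""
    obs = [Observation("SpO2", v, t) for t, v in spo2]
    obs += [Observation(f, v, t) for f, v, t in observations]
    evs = [Event(et, code, t) for et, code, t in events]
    return Encounter(
        patient_id=patient_id,
        admission_time=0.0,
        discharge_time=discharge,
        observations=sorted(obs, key=lambda o: o.time),
        events=sorted(evs, key=lambda e: e.time),
        hospital_id=hospital,
        age=age,
        sex=sex,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=300, ards_prevalence=0.05, seed=42))


@pytest.fixture(scope="session")
def identity_stats():
    return NormalizationStats.identity()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
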