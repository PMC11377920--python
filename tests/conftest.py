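import numpy as np
import pandas as pd
import pytest

import hotpath as hp


@pytest.fixture(scope="session")
def rennes_config():
    """Default generator configuration at roughly the Rennes sample size."""
    return hp.default_rennes_config(n_households=7800)


@pytest.fixture(scope="session")
def rennes_survey(rennes_config):
    survey, truth = hp.generate_survey(rennes_config)
    return survey, truth


@pytest.fixture(scope="session")
def rennes_frame(rennes_survey):
    survey, _ = rennes_survey
    return hp.build_analysis_frame(survey)


@pytest.fixture
def toy_survey():
    """Four-person handmade survey covering both zones and all modes."""
    households = pd.DataFrame(
        {
            "household_id": ["H1", "H2", "H3"],
            "zone": ["commune", "suburbaine", "suburbaine"],
            "n_cars": [0, 1, 2],
            "weight": [1.0, 1.5, 0.8],
        }
    )
    persons = pd.DataFrame(
        {
            "person_id": ["P1", "P2", "P3", "P4"],
            "household_id": ["H1", "H2", "H3", "H3"],
            "sex": ["F", "M", "F", "M"],
            "age": [30, 45, 60, 22],
            "education": [6, 4, 2, 5],
            "walk_freq": ["week", "never", None, "month"],
            "cycle_freq": ["month", None, "week", "never"],
            "weight": [1.0, 2.0, 1.0, 0.5],
        }
    )
    trips = pd.DataFrame(
        {
            "trip_id": ["T1", "T2", "T3", "T4", "T5"],
            "person_id": ["P1", "P1", "P2", "P3", "P4"],
            "mode": ["walk", "cycle", "car_moto", "transit", "walk"],
            "duration_min": [30.0, 20.0, 25.0, 40.0, 15.0],
        }
    )
    return hp.Survey(households=households, persons=persons, trips=trips)


def make_metric_frame(
    active, weights, participant=None, responded=None, met_hours_walk=None
):
    """Minimal analysis frame for metric unit tests."""
    n = len(active)
    active = np.asarray(active, dtype=bool)
    if participant is None:
        participant = active
    participant = np.asarray(participant, dtype=float)
    if responded is None:
        responded = np.ones(n, dtype=bool)
    if met_hours_walk is None:
        met_hours_walk = np.where(active, 1.0, 0.0)
    met_hours_walk = np.asarray(met_hours_walk, dtype=float)
    return pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n)],
            "weight": np.asarray(weights, dtype=float),
            "active_day_walk": active,
            "active_day_cycle": np.zeros(n, dtype=bool),
            "active_day_any": active,
            "met_hours_walk": met_hours_walk,
            "met_hours_cycle": np.zeros(n),
            "met_hours_active": met_hours_walk,
            "responded_walk": np.asarray(responded, dtype=bool),
            "responded_cycle": np.asarray(responded, dtype=bool),
            "weekly_participant_walk": np.where(responded, participant, np.nan),
            "weekly_participant_cycle": np.where(responded, 0.0, np.nan),
        }
    )
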