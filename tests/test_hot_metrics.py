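"""HOT metric estimators: hand-checkable values, weighting invariances,
the travel-activity identity, and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

import hotpath as hp
from hotpath.hot_metrics import EmptyScopeError, MetricEstimate, kish_n_eff

from conftest import make_metric_frame


def test_weighted_prevalence_hand_example():
    """Weights (1,1,2,4) and indicators (1,0,1,0) give 3/8."""
    frame = make_metric_frame(active=[1, 0, 1, 0], weights=[1, 1, 2, 4])
    est = hp.prevalence(frame)
    assert est.value == pytest.approx(0.375)
    assert est.n == 4


def test_prevalence_all_inactive_degenerate_ci():
    frame = make_metric_frame(active=[0, 0, 0], weights=[1, 2, 3])
    est = hp.prevalence(frame)
    assert est.value == 0.0
    assert (est.ci_low, est.ci_high) == (0.0, 0.0)


def test_participation_inner_city_category_counts():
    """Unweighted four-category counts reproduce the published inner-city
    weekly shares: walking 935/1229 = 76%, cycling 203/1229 = 17%."""
    walk_counts = {"week": 935, "month": 114, "year": 134, "never": 46}
    cycle_counts = {"week": 203, "month": 101, "year": 216, "never": 709}
    n = sum(walk_counts.values())
    walk_week = np.repeat(
        [1.0, 0.0], [walk_counts["week"], n - walk_counts["week"]]
    )
    cycle_week = np.repeat(
        [1.0, 0.0], [cycle_counts["week"], n - cycle_counts["week"]]
    )
    frame = make_metric_frame(active=np.zeros(n), weights=np.ones(n), participant=walk_week)
    frame["weekly_participant_cycle"] = cycle_week
    walk = hp.participation(frame, "walk")
    cycle = hp.participation(frame, "cycle")
    assert round(walk.value * 100) == 76
    assert round(cycle.value * 100) == 17


def test_participation_all_week_is_one():
    frame = make_metric_frame(active=[1, 1], weights=[1, 1], participant=[1, 1])
    assert hp.participation(frame, "walk").value == 1.0


def test_participation_excludes_nonresponders():
    frame = make_metric_frame(
        active=[0, 0, 0, 0],
        weights=[1, 1, 1, 1],
        participant=[1, 0, 1, 1],
        responded=[True, True, False, False],
    )
    est = hp.participation(frame, "walk")
    assert est.n == 2
    assert est.value == pytest.approx(0.5)


def test_frequency_published_ratios():
    def m(v):
        return MetricEstimate(value=v, ci_low=v, ci_high=v, n=1, n_eff=1)

    assert round(hp.frequency(m(0.036), m(0.097)), 1) == 0.4
    assert round(hp.frequency(m(0.461), m(0.621)), 1) == 0.7
    assert hp.frequency(m(0.3), m(0.3)) == 1.0


def test_frequency_zero_participation_raises():
    m = MetricEstimate(value=0.2, ci_low=0, ci_high=1, n=1, n_eff=1)
    z = MetricEstimate(value=0.0, ci_low=0, ci_high=0, n=1, n_eff=1)
    with pytest.raises(ZeroDivisionError):
        hp.frequency(m, z)


def test_frequency_above_one_warns():
    m = MetricEstimate(value=0.5, ci_low=0, ci_high=1, n=1, n_eff=1)
    s = MetricEstimate(value=0.25, ci_low=0, ci_high=1, n=1, n_eff=1)
    with pytest.warns(UserWarning, match="exceeds 1"):
        assert hp.frequency(m, s) == pytest.approx(2.0)


def test_intensity_single_participant():
    """Diary 1.5 MET-h at frequency 0.5 scales to 1.5 * 7 * 0.5 = 5.25."""
    frame = make_metric_frame(active=[1], weights=[1.0], met_hours_walk=[1.5])
    est = hp.intensity(frame, {"walk": 0.5, "cycle": 1.0})
    assert est.value == pytest.approx(5.25)


def test_equal_weights_match_unweighted():
    rng = np.random.default_rng(0)
    active = rng.uniform(size=40) < 0.4
    met = np.where(active, rng.uniform(0.5, 3.0, size=40), 0.0)
    f1 = make_metric_frame(active=active, weights=np.full(40, 3.7), met_hours_walk=met)
    f2 = make_metric_frame(active=active, weights=np.ones(40), met_hours_walk=met)
    for fn in (
        lambda f: hp.prevalence(f).value,
        lambda f: hp.intensity(f, {"walk": 0.6, "cycle": 0.6}).value,
        lambda f: hp.population_travel_activity(f).value,
    ):
        assert fn(f1) == pytest.approx(fn(f2), rel=1e-12)


def test_travel_activity_identity(rennes_frame):
    """TA = intensity x participation exactly, when the weekly scaling
    uses the combined frequency f = prevalence / participation."""
    prev = hp.prevalence(rennes_frame)
    part = hp.participation(rennes_frame)
    f = hp.frequency(prev, part)
    inten = hp.intensity(rennes_frame, {"walk": f, "cycle": f})
    ta = hp.population_travel_activity(rennes_frame)
    assert inten.value * part.value == pytest.approx(ta.value, rel=1e-9)


def test_population_travel_activity_values():
    frame = make_metric_frame(active=[1], weights=[2.0], met_hours_walk=[3.5])
    assert hp.population_travel_activity(frame).value == pytest.approx(24.5)
    empty = make_metric_frame(active=[0, 0], weights=[1, 1])
    assert hp.population_travel_activity(empty).value == 0.0


def test_mode_share_published_example():
    trips = pd.DataFrame(
        {
            "trip_id": [f"T{i}" for i in range(100)],
            "person_id": ["P0"] * 100,
            "mode": ["car_moto"] * 40 + ["walk"] * 35 + ["cycle"] * 9 + ["transit"] * 16,
            "duration_min": [10.0] * 100,
        }
    )
    shares = hp.mode_share(trips)
    assert shares["car_moto"] == pytest.approx(0.40)
    assert shares["walk"] == pytest.approx(0.35)
    assert shares["cycle"] == pytest.approx(0.09)
    assert shares["transit"] == pytest.approx(0.16)
    assert shares.sum() == pytest.approx(1.0)
    # duplicating every trip leaves shares unchanged
    doubled = hp.mode_share(pd.concat([trips, trips], ignore_index=True))
    assert np.allclose(doubled.to_numpy(), shares.to_numpy())


def test_mode_share_single_mode():
    trips = pd.DataFrame(
        {"trip_id": ["T0"], "person_id": ["P0"], "mode": ["walk"], "duration_min": [5.0]}
    )
    assert hp.mode_share(trips)["walk"] == 1.0


def test_empty_subgroup_raises(rennes_frame):
    with pytest.raises(EmptyScopeError):
        hp.prevalence(rennes_frame, subgroup_filter=np.zeros(len(rennes_frame), bool))


def test_proportion_cis_clipped():
    frame = make_metric_frame(active=[1, 1, 0], weights=[1, 1, 1])
    est = hp.prevalence(frame)
    assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_brute_force_oracle_small_frames(seed):
    """On frames of <= 20 rows every estimator equals a direct
    enumeration of the weighted sums."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 21))
    w = rng.uniform(0.2, 3.0, size=n)
    active = rng.uniform(size=n) < 0.5
    if not active.any():
        active[0] = True
    met = np.where(active, rng.uniform(0.2, 4.0, size=n), 0.0)
    part = (rng.uniform(size=n) < 0.6).astype(float)
    resp = rng.uniform(size=n) < 0.8
    if not resp.any():
        resp[0] = True
    frame = make_metric_frame(
        active=active, weights=w, participant=part, responded=resp, met_hours_walk=met
    )

    assert hp.prevalence(frame).value == pytest.approx(
        sum(w[i] for i in range(n) if active[i]) / w.sum()
    )
    num = sum(w[i] for i in range(n) if resp[i] and part[i] == 1.0)
    den = sum(w[i] for i in range(n) if resp[i])
    assert hp.participation(frame, "walk").value == pytest.approx(num / den)
    f = 0.7
    act_idx = [i for i in range(n) if active[i]]
    weekly = {i: met[i] * 7 * f for i in act_idx}
    inten = sum(w[i] * weekly[i] for i in act_idx) / sum(w[i] for i in act_idx)
    assert hp.intensity(frame, {"walk": f, "cycle": f}).value == pytest.approx(inten)
    ta = 7 * sum(w[i] * met[i] for i in range(n)) / w.sum()
    assert hp.population_travel_activity(frame).value == pytest.approx(ta)
    assert kish_n_eff(w) == pytest.approx(w.sum() ** 2 / (w**2).sum())
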