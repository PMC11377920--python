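"""Comparative risk assessment chain: ERF fitting against a grid-search
oracle, baseline simulation, the mortality-change formula, the
deaths-DALY link, and burden/cost translation."""

import numpy as np
import pytest

import hotpath as hp
from hotpath import BaselineActivitySpec, BurdenInputs, CostModel, DoseResponseTable, ExposureResponse
from hotpath.health_impact import relative_risk_change_distributional


def synthetic_table(alpha=0.107, p=0.436, x=(5.0, 10.0, 20.0, 40.0)):
    x = np.asarray(x)
    return DoseResponseTable(
        exposure=tuple(x), relative_risk=tuple(np.exp(-alpha * x**p))
    )


def test_erf_exact_recovery_from_noiseless_points():
    erf = hp.fit_erf(synthetic_table())
    assert erf.alpha_shape == pytest.approx(0.107, abs=1e-6)
    assert erf.p_power == pytest.approx(0.436, abs=1e-6)


def test_erf_rr_scale_objective_agrees_on_noiseless_points():
    erf = hp.fit_erf(synthetic_table(), objective="rr")
    assert erf.alpha_shape == pytest.approx(0.107, abs=1e-5)
    assert erf.p_power == pytest.approx(0.436, abs=1e-5)


def test_erf_agrees_with_grid_search_oracle():
    """Dense brute-force grid over (alpha, p) on a noisy 4-point table."""
    rng = np.random.default_rng(0)
    x = np.array([4.0, 9.0, 18.0, 35.0])
    rr = np.exp(-0.09 * x**0.5) * np.exp(rng.normal(0, 0.01, size=4))
    table = DoseResponseTable(exposure=tuple(x), relative_risk=tuple(rr))
    fitted = hp.fit_erf(table)

    y = np.log(rr)
    p_grid = np.linspace(0.05, 2.0, 2000)
    best = (np.inf, None, None)
    for p in p_grid:
        xp = x**p
        a = -float(xp @ y) / float(xp @ xp)
        sse = float(((y + a * xp) ** 2).sum())
        if sse < best[0]:
            best = (sse, a, p)
    assert fitted.p_power == pytest.approx(best[2], abs=2e-3)
    assert fitted.alpha_shape == pytest.approx(best[1], rel=2e-2)


def test_erf_bundled_cohort_table():
    """The bundled dose-response transcription yields shape and power
    close to the published pair (0.107, 0.436); exact agreement is not
    attainable because the source's fitting protocol is unpublished."""
    erf = hp.fit_erf(hp.AREM_DOSE_RESPONSE)
    assert erf.alpha_shape == pytest.approx(0.107, abs=0.01)
    assert erf.p_power == pytest.approx(0.436, abs=0.015)


def test_erf_validation():
    with pytest.raises(ValueError, match="positive"):
        DoseResponseTable(exposure=(1.0, 2.0, 3.0), relative_risk=(1.0, -0.5, 0.3))
    with pytest.raises(ValueError, match="3 rows"):
        hp.fit_erf(DoseResponseTable(exposure=(1.0, 2.0), relative_risk=(1.0, 0.9)))


def test_erf_shape_properties():
    erf = hp.RENNES_ERF
    assert erf.relative_risk(0.0) == 1.0
    xs = np.linspace(0.1, 80, 200)
    rr = erf.relative_risk(xs)
    assert (np.diff(rr) < 0).all()


@pytest.mark.parametrize(
    "spec, expected_median",
    [
        (BaselineActivitySpec(intervals=((10.0, 14.0),), proportions=(1.0,), n_sim=20_000, seed=1), 12.0),
        (
            BaselineActivitySpec(
                intervals=((0.0, 1.0), (1.0, 3.0)), proportions=(0.5, 0.5), n_sim=20_000, seed=2
            ),
            1.0,
        ),
    ],
)
def test_baseline_simulation_matches_analytic_median(spec, expected_median):
    assert spec.analytic_median() == pytest.approx(expected_median)
    draws_iqr = 0.5 * (spec.intervals[-1][1] - spec.intervals[0][0])  # generous bound
    tol = 3 * max(draws_iqr, 1e-6) / np.sqrt(spec.n_sim)
    assert hp.simulate_baseline(spec) == pytest.approx(expected_median, abs=max(tol, 0.05))


def test_baseline_bundled_intervals_give_twelve():
    """The bundled activity-interval mixture simulates to the published
    baseline of ~12 MET-h/week."""
    assert hp.AREM_ACTIVITY_INTERVALS.analytic_median() == pytest.approx(12.0, abs=1e-9)
    median = hp.simulate_baseline(hp.AREM_ACTIVITY_INTERVALS)
    assert median == pytest.approx(12.0, abs=0.5)


def test_baseline_spec_validation():
    with pytest.raises(ValueError, match="sum"):
        BaselineActivitySpec(intervals=((0.0, 1.0),), proportions=(0.9,))
    with pytest.raises(ValueError, match="overlap"):
        BaselineActivitySpec(
            intervals=((0.0, 2.0), (1.0, 3.0)), proportions=(0.5, 0.5)
        )


def test_rho_zero_change_is_zero():
    assert hp.relative_risk_change(12.0, 0.0) == 0.0


@pytest.mark.parametrize(
    "delta, expected",
    [(3.91, -0.0405), (1.28, -0.0142)],
)
def test_rho_printed_formula_values(delta, expected):
    """Direct evaluation of rho = R(x_b + dTA)/R(x_b) - 1 with the
    published constants (alpha 0.107, p 0.436, x_b 12)."""
    assert hp.relative_risk_change(12.0, delta) == pytest.approx(expected, abs=1e-4)


def test_rho_negative_exposure_rejected():
    with pytest.raises(ValueError):
        hp.relative_risk_change(12.0, -15.0)


def test_rho_monotone_and_concave():
    deltas = np.linspace(0.1, 10, 50)
    rhos = np.array([hp.relative_risk_change(12.0, d) for d in deltas])
    assert (np.diff(rhos) < 0).all()  # more activity, larger reduction
    assert (rhos > -1).all() and (rhos < 0).all()
    # diminishing returns: rho(2d) > 2 rho(d) in signed value
    for d in (0.5, 1.0, 2.0, 4.0):
        assert hp.relative_risk_change(12.0, 2 * d) > 2 * hp.relative_risk_change(12.0, d)


def test_distributional_diagnostic_close_to_mean_shortcut():
    rng = np.random.default_rng(3)
    x = rng.uniform(4, 20, size=10_000)
    shortcut = hp.relative_risk_change(float(np.median(x)), 2.0)
    integrated = relative_risk_change_distributional(x, 2.0)
    assert integrated == pytest.approx(shortcut, abs=5e-3)


def test_deaths_daly_link_exact_half():
    """DALY changes constructed as exactly half the death changes."""
    deaths = np.array([100.0, 104.0, 99.84, 103.83])
    changes = np.diff(deaths) / deaths[:-1]
    dalys = np.empty_like(deaths)
    dalys[0] = 500.0
    for i, c in enumerate(changes):
        dalys[i + 1] = dalys[i] * (1 + 0.5 * c)
    k, ci = hp.fit_deaths_daly_link(deaths, dalys)
    assert k == pytest.approx(0.5, abs=1e-12)
    assert ci[0] == pytest.approx(0.5, abs=1e-9)


def test_deaths_daly_link_hand_example():
    """Zero-intercept slope for changes (0.02,-0.01,0.03) vs
    (0.011,-0.004,0.012): sum(xy)/sum(x^2) = 0.443."""
    deaths = 100 * np.cumprod([1.0, 1.02, 0.99, 1.03])
    dalys = 100 * np.cumprod([1.0, 1.011, 0.996, 1.012])
    k, _ = hp.fit_deaths_daly_link(deaths, dalys)
    assert k == pytest.approx(0.443, abs=0.001)


def test_deaths_daly_link_recovery_with_noise():
    rng = np.random.default_rng(4)
    true_k = 0.45
    dx = rng.normal(0, 0.02, size=29)
    dy = true_k * dx + rng.normal(0, 0.004, size=29)
    deaths = 100 * np.cumprod(np.concatenate([[1.0], 1 + dx]))
    dalys = 900 * np.cumprod(np.concatenate([[1.0], 1 + dy]))
    k, ci = hp.fit_deaths_daly_link(deaths, dalys)
    assert ci[0] <= true_k <= ci[1]


def test_deaths_daly_link_validation():
    with pytest.raises(ValueError, match="3"):
        hp.fit_deaths_daly_link([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="positive"):
        hp.fit_deaths_daly_link([1.0, 0.0, 2.0], [1.0, 1.0, 1.0])


def test_averted_burden_reproduces_published_row():
    """rho = -0.0405 on the derived Rennes baselines returns the
    published ~(25 deaths, 1051 DALYs)."""
    deaths, dalys = hp.averted_burden(-0.0405, hp.RENNES_BURDEN)
    assert deaths == pytest.approx(25, abs=1)
    assert dalys == pytest.approx(1051, abs=2)


def test_averted_burden_zero_and_linearity():
    assert hp.averted_burden(0.0, hp.RENNES_BURDEN) == (0.0, 0.0)
    doubled = BurdenInputs(
        annual_deaths=617.0, annual_dalys=2 * 57_700.0, population=300_000.0, k_link=0.45
    )
    _, d1 = hp.averted_burden(-0.02, hp.RENNES_BURDEN)
    _, d2 = hp.averted_burden(-0.02, doubled)
    assert d2 == pytest.approx(2 * d1)


def test_averted_burden_positive_rho_warns():
    with pytest.warns(UserWarning, match="adds burden"):
        deaths, dalys = hp.averted_burden(0.01, hp.RENNES_BURDEN)
    assert deaths < 0 and dalys < 0


def test_cost_savings_published_row():
    """714 averted DALYs at the derived central rate is ~$49.6M,
    i.e. the published $50M after rounding to whole millions."""
    costs = hp.cost_savings(714, hp.DAROUDI_COST)
    assert costs["central"] / 1e6 == pytest.approx(49.6, abs=0.1)
    assert round(costs["central"] / 1e6) == 50
    assert costs["low"] <= costs["central"] <= costs["high"]


def test_cost_savings_zero():
    costs = hp.cost_savings(0.0, hp.DAROUDI_COST)
    assert costs == {"central": 0.0, "low": 0.0, "high": 0.0}


def test_cost_model_ordering_enforced():
    with pytest.raises(ValueError):
        CostModel(usd_per_daly_central=10.0, usd_per_daly_low=20.0, usd_per_daly_high=30.0)


def test_full_chain_ratio_consistency():
    """Across the published activity changes, averted-death ratios track
    the rho ratios within 10% (rounding-limited)."""
    deltas = [3.91, 2.57, 1.55, 1.43, 1.28]
    printed_deaths = [25, 17, 10, 10, 9]
    rhos = [hp.relative_risk_change(12.0, d) for d in deltas]
    for i in range(1, len(deltas)):
        assert rhos[i] / rhos[0] == pytest.approx(
            printed_deaths[i] / printed_deaths[0], rel=0.10
        )


def test_assess_impact_end_to_end():
    result = hp.assess_impact(3.91)
    assert result.rho == pytest.approx(-0.0405, abs=1e-4)
    assert round(result.averted_deaths) == 25
    assert result.cost_saved_low <= result.cost_saved_central <= result.cost_saved_high
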