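"""Health-oriented transportation (HOT) active-travel metrics.

Survey-weighted estimators of the five HOT metrics, each returned as a
:class:`MetricEstimate` with a 95% confidence interval:

prevalence
    proportion of persons with at least one walk or cycle trip on the
    one-day diary (an observed one-day snapshot).
participation
    proportion answering "several days per week" on the walk/cycle
    frequency questionnaire, among those who answered it.
frequency
    prevalence / participation — interpretable as the fraction of days a
    weekly participant is actually active, and the factor that scales the
    one-day diary up to a week.
intensity
    mean weekly active-travel MET-hours among active travelers, obtained
    by scaling each prevalent person's diary MET-hours by ``7 x f_mode``.
travel activity (TA)
    population mean weekly active-travel MET-hours, ``7 x`` the weighted
    mean diary MET-hours over everyone.

These satisfy the identity ``TA = intensity x participation`` when a
single combined frequency is used for the weekly scaling.

Confidence intervals use a normal approximation with the Kish effective
sample size ``n_eff = (sum w)^2 / sum w^2``; proportion intervals are
clipped to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .survey_model import ACTIVE_MODES, MODES

__all__ = [
    "MetricEstimate",
    "HotSummary",
    "EmptyScopeError",
    "kish_n_eff",
    "prevalence",
    "participation",
    "frequency",
    "intensity",
    "population_travel_activity",
    "mode_share",
    "compute_hot_summary",
]

_Z95 = 1.959963984540054


class EmptyScopeError(ValueError):
    """No observations remain in the requested scope."""


@dataclass(frozen=True)
class MetricEstimate:
    """A weighted point estimate with a 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    n: int
    n_eff: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HotSummary:
    """The full set of HOT metrics for one population scope."""

    prevalence_overall: MetricEstimate
    prevalence_by_mode: dict[str, MetricEstimate]
    participation_overall: MetricEstimate
    participation_by_mode: dict[str, MetricEstimate]
    frequency_overall: float
    frequency_by_mode: dict[str, float]
    intensity: MetricEstimate
    travel_activity: MetricEstimate

    def to_dict(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            out[key] = val
        return out


def kish_n_eff(weights: np.ndarray) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2``."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def _weighted_proportion(indicator: np.ndarray, weights: np.ndarray) -> MetricEstimate:
    ind = np.asarray(indicator, dtype=float)
    w = np.asarray(weights, dtype=float)
    if ind.size == 0:
        raise EmptyScopeError("no observations in scope")
    p = float(np.average(ind, weights=w))
    n_eff = kish_n_eff(w)
    se = np.sqrt(max(p * (1.0 - p), 0.0) / n_eff)
    return MetricEstimate(
        value=p,
        ci_low=float(np.clip(p - _Z95 * se, 0.0, 1.0)),
        ci_high=float(np.clip(p + _Z95 * se, 0.0, 1.0)),
        n=int(ind.size),
        n_eff=n_eff,
    )


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> MetricEstimate:
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        raise EmptyScopeError("no observations in scope")
    m = float(np.average(x, weights=w))
    n_eff = kish_n_eff(w)
    var = float(np.average((x - m) ** 2, weights=w))
    se = np.sqrt(var / n_eff)
    return MetricEstimate(
        value=m,
        ci_low=m - _Z95 * se,
        ci_high=m + _Z95 * se,
        n=int(x.size),
        n_eff=n_eff,
    )


def _scope(frame: pd.DataFrame, subgroup_filter: pd.Series | np.ndarray | None) -> pd.DataFrame:
    if subgroup_filter is None:
        return frame
    scoped = frame.loc[np.asarray(subgroup_filter, dtype=bool)]
    if scoped.empty:
        raise EmptyScopeError("empty subgroup after filtering")
    return scoped


def prevalence(
    frame: pd.DataFrame,
    mode: str | None = None,
    subgroup_filter: pd.Series | np.ndarray | None = None,
) -> MetricEstimate:
    """Weighted one-day active-travel prevalence.

    With ``mode=None`` a person counts as prevalent if they logged at
    least one walk *or* cycle trip on the diary day; with a mode, only
    trips of that mode count.  The denominator is every person in scope,
    questionnaire respondent or not.
    """
    scoped = _scope(frame, subgroup_filter)
    col = "active_day_any" if mode is None else f"active_day_{mode}"
    return _weighted_proportion(scoped[col].to_numpy(), scoped["weight"].to_numpy())


def participation(
    frame: pd.DataFrame,
    mode: str | None = None,
    subgroup_filter: pd.Series | np.ndarray | None = None,
) -> MetricEstimate:
    """Weighted weekly active-travel participation.

    The denominator contains questionnaire respondents only.  For a
    single mode, respondents to that mode's question; overall, persons
    who answered at least one of the two questions, counting those who
    answered "several days per week" for walking or cycling.
    """
    scoped = _scope(frame, subgroup_filter)
    if mode is not None:
        resp = scoped[f"responded_{mode}"].to_numpy()
        if not resp.any():
            raise EmptyScopeError(f"no {mode} questionnaire respondents in scope")
        ind = scoped.loc[resp, f"weekly_participant_{mode}"].to_numpy() == 1.0
        w = scoped.loc[resp, "weight"].to_numpy()
        return _weighted_proportion(ind, w)
    resp = (scoped["responded_walk"] | scoped["responded_cycle"]).to_numpy()
    if not resp.any():
        raise EmptyScopeError("no questionnaire respondents in scope")
    sub = scoped.loc[resp]
    ind = (
        (sub["weekly_participant_walk"] == 1.0)
        | (sub["weekly_participant_cycle"] == 1.0)
    ).to_numpy()
    return _weighted_proportion(ind, sub["weight"].to_numpy())


def frequency(prevalence: MetricEstimate, participation: MetricEstimate) -> float:
    """HOT frequency: the ratio prevalence / participation.

    Values above 1 (possible in small subgroups, where the one-day
    snapshot overshoots the reported weekly behaviour) trigger a warning
    but are reported as computed.
    """
    if participation.value <= 0:
        raise ZeroDivisionError(
            "frequency is undefined when participation is zero"
        )
    f = prevalence.value / participation.value
    if f > 1.0:
        warnings.warn(
            f"frequency {f:.3f} exceeds 1; the one-day snapshot overshoots "
            "the reported weekly participation in this scope",
            stacklevel=2,
        )
    return f


def intensity(
    frame: pd.DataFrame,
    f_by_mode: dict[str, float],
    subgroup_filter: pd.Series | np.ndarray | None = None,
) -> MetricEstimate:
    """Travel intensity: mean weekly MET-hours among active travelers.

    Each person prevalent on the diary day contributes
    ``sum_m diary_MET_hours_m x 7 x f_m`` — their single observed day
    scaled to a week by the mode's frequency.  Frequencies above 1 are
    truncated to 1 for this scaling only.
    """
    scoped = _scope(frame, subgroup_filter)
    active = scoped.loc[scoped["active_day_any"]]
    if active.empty:
        raise EmptyScopeError("no active travelers in scope")
    weekly = np.zeros(len(active))
    for mode in ACTIVE_MODES:
        f = min(f_by_mode[mode], 1.0)
        weekly = weekly + active[f"met_hours_{mode}"].to_numpy() * 7.0 * f
    return _weighted_mean(weekly, active["weight"].to_numpy())


def population_travel_activity(
    frame: pd.DataFrame,
    subgroup_filter: pd.Series | np.ndarray | None = None,
) -> MetricEstimate:
    """Population travel activity: 7 x weighted mean diary MET-hours."""
    scoped = _scope(frame, subgroup_filter)
    weekly = 7.0 * scoped["met_hours_active"].to_numpy()
    return _weighted_mean(weekly, scoped["weight"].to_numpy())


def mode_share(
    trips: pd.DataFrame,
    person_weights: pd.Series | None = None,
) -> pd.Series:
    """Weighted share of diary trips per mode (sums to 1).

    *person_weights* maps ``person_id`` to a survey weight; omitted, all
    trips count equally.
    """
    if trips.empty:
        raise EmptyScopeError("no trips")
    if person_weights is None:
        w = np.ones(len(trips))
    else:
        w = trips["person_id"].map(person_weights).to_numpy(dtype=float)
        if np.isnan(w).any():
            raise ValueError("trips reference persons without weights")
    totals = pd.Series(0.0, index=list(MODES))
    sums = pd.Series(w).groupby(trips["mode"].to_numpy()).sum()
    totals.loc[sums.index] = sums.to_numpy()
    return totals / totals.sum()


def compute_hot_summary(
    frame: pd.DataFrame,
    subgroup_filter: pd.Series | np.ndarray | None = None,
) -> HotSummary:
    """Compute all HOT metrics for one scope."""
    prev_by_mode = {m: prevalence(frame, m, subgroup_filter) for m in ACTIVE_MODES}
    part_by_mode = {m: participation(frame, m, subgroup_filter) for m in ACTIVE_MODES}
    prev = prevalence(frame, None, subgroup_filter)
    part = participation(frame, None, subgroup_filter)
    f_by_mode = {
        m: frequency(prev_by_mode[m], part_by_mode[m]) for m in ACTIVE_MODES
    }
    return HotSummary(
        prevalence_overall=prev,
        prevalence_by_mode=prev_by_mode,
        participation_overall=part,
        participation_by_mode=part_by_mode,
        frequency_overall=frequency(prev, part),
        frequency_by_mode=f_by_mode,
        intensity=intensity(frame, f_by_mode, subgroup_filter),
        travel_activity=population_travel_activity(frame, subgroup_filter),
    )


def summary_to_json(summary: HotSummary, path: str | Path) -> None:
    """Serialise a :class:`HotSummary` to a JSON file."""
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True))
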