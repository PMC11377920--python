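"""Synthetic one-day household travel survey generator.

Emulates a French EMD-style household travel survey (households, persons,
one-day trip diary, walk/cycle frequency questionnaire, survey weights)
with *known* latent ground truth, so that every downstream estimator can
be tested against analytic expectations.

Latent weekly-behaviour model, per person and per active mode
(walk, cycle):

1. weekly participation is Bernoulli(pi), with pi given by a logistic
   model on residential zone and household car access (odds ratios are
   part of the configuration);
2. conditional on participating, the number of active days per week is an
   integer in 1..7 drawn from a configured distribution;
3. the single diary day is exchangeable across the week: a participant
   with ``d`` active days logs one or more trips in the mode with
   probability ``d/7`` on the diary day.

By construction the population one-day prevalence of a mode equals
``E[pi * d/7]``, weekly participation equals ``E[pi]``, and the HOT
frequency metric (prevalence / participation) recovers the mean fraction
of active days among participants — the identity the estimators are
tested against.

The frequency questionnaire answer is ``week`` if and only if the person
is a weekly participant; non-participants answer from a configured
multinomial over ``month``/``year``/``never``.  Questionnaire nonresponse
is drawn independently up front as a latent *response class*, and the
class is allowed to carry its own participation level: surveys of this
kind show far more diary activity among the subsample that answered the
frequency questions than among those who skipped them, so informative
nonresponse is needed to make overall diary prevalence and
respondent-only participation both match their observed levels.

Walk and cycle participation are positively associated through a single
multiplicative association factor on the joint probability.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats

from .survey_model import ACTIVE_MODES, Survey

__all__ = [
    "ZoneDemographics",
    "ModeLatentConfig",
    "LatentTravelConfig",
    "ActiveTripConfig",
    "OtherTripConfig",
    "TripModelConfig",
    "GeneratorConfig",
    "generate_survey",
    "default_rennes_config",
    "write_truth",
]

_PROB_TOL = 1e-9


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ZoneDemographics(_Model):
    """Per-zone person demographics."""

    sex_male_prop: float = Field(ge=0.0, le=1.0)
    age_mean: float = Field(gt=0.0)
    age_sd: float = Field(gt=0.0)
    #: probabilities of the six education codes 1..6
    education_probs: list[float] = Field(min_length=6, max_length=6)

    @model_validator(mode="after")
    def _check_probs(self) -> "ZoneDemographics":
        if any(p < 0 for p in self.education_probs):
            raise ValueError("education_probs: negative probability")
        if abs(sum(self.education_probs) - 1.0) > _PROB_TOL:
            raise ValueError("education_probs must sum to 1")
        return self


class ModeLatentConfig(_Model):
    """Latent weekly-participation model for one active mode.

    The participation probability of a person in response class ``c`` is
    ``invlogit(intercept[c] + log(or_commune)*commune + log(or_no_car)*no_car)``.
    """

    intercept_respondent: float
    intercept_nonrespondent: float
    or_commune: float = Field(gt=0.0)
    or_no_car: float = Field(gt=0.0)
    #: probabilities of 1..7 active days per week, conditional on participation
    active_days_probs: list[float] = Field(min_length=7, max_length=7)

    @model_validator(mode="after")
    def _check_days(self) -> "ModeLatentConfig":
        if any(p < 0 for p in self.active_days_probs):
            raise ValueError("active_days_probs: negative probability")
        if abs(sum(self.active_days_probs) - 1.0) > _PROB_TOL:
            raise ValueError("active_days_probs must sum to 1")
        return self

    def mean_active_days(self) -> float:
        return float(np.dot(np.arange(1, 8), self.active_days_probs))


class LatentTravelConfig(_Model):
    walk: ModeLatentConfig
    cycle: ModeLatentConfig
    #: joint P(walk & cycle participation) = assoc * P(walk) * P(cycle),
    #: applied per person; 1.0 means independence.
    cycle_walk_assoc: float = Field(default=1.0, gt=0.0)
    #: answer distribution over (month, year, never) among non-participants
    nonparticipant_answer_probs: list[float] = Field(
        default=[0.2, 0.4, 0.4], min_length=3, max_length=3
    )

    @model_validator(mode="after")
    def _check_answers(self) -> "LatentTravelConfig":
        if any(p < 0 for p in self.nonparticipant_answer_probs):
            raise ValueError("nonparticipant_answer_probs: negative probability")
        if abs(sum(self.nonparticipant_answer_probs) - 1.0) > _PROB_TOL:
            raise ValueError("nonparticipant_answer_probs must sum to 1")
        return self


class ActiveTripConfig(_Model):
    """Trip generation for an active mode on an active diary day."""

    #: mean trips on an active day (zero-truncated Poisson; must exceed 1)
    trips_per_active_day: float = Field(gt=1.0)
    #: multiplier on the trip mean for inner-city residents
    commune_trips_multiplier: float = Field(default=1.0, gt=0.0)
    duration_log_mean: float
    duration_log_sd: float = Field(gt=0.0)


class OtherTripConfig(_Model):
    """Trip generation for a non-active mode (plain Poisson per day)."""

    trips_per_day: float = Field(ge=0.0)
    duration_log_mean: float
    duration_log_sd: float = Field(gt=0.0)


class TripModelConfig(_Model):
    walk: ActiveTripConfig
    cycle: ActiveTripConfig
    car_moto: OtherTripConfig
    transit: OtherTripConfig
    other: OtherTripConfig


class GeneratorConfig(_Model):
    """Full configuration of the synthetic survey generator.

    A fixed ``seed`` makes the generated survey byte-identical across
    calls; all sub-streams (households, persons, trips, weights) are
    derived deterministically from it.
    """

    n_households: int = Field(gt=0)
    #: mean surveyed persons per household (zero-truncated Poisson; > 1)
    persons_per_household_mean: float = Field(gt=1.0)
    #: probability a household is in the inner-city zone
    zone_split: float = Field(ge=0.0, le=1.0)
    demographics: dict[Literal["commune", "suburbaine"], ZoneDemographics]
    #: per-zone probability that the household has >= 1 car
    car_access: dict[Literal["commune", "suburbaine"], float]
    latent_travel: LatentTravelConfig
    trip_model: TripModelConfig
    #: probability a person skips the frequency questionnaire (the latent
    #: response class; participation intercepts differ by class)
    nonresponse_prob: float = Field(ge=0.0, le=1.0)
    #: sigma of the lognormal survey-weight distribution (mean scaled to 1)
    weight_log_sd: float = Field(default=0.0, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for zone in ("commune", "suburbaine"):
            if zone not in self.demographics:
                raise ValueError(f"demographics: missing zone {zone!r}")
            if zone not in self.car_access:
                raise ValueError(f"car_access: missing zone {zone!r}")
            p = self.car_access[zone]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"car_access[{zone!r}] must be in [0, 1]")
        return self


def _invlogit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _ztp_rate(mean: float) -> float:
    """Poisson rate lambda whose zero-truncated mean equals *mean* (> 1)."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    return float(
        optimize.brentq(
            lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-12, 10 * mean, xtol=1e-12
        )
    )


def _ztp(rng: np.random.Generator, mean: float | np.ndarray, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws with truncated mean ``mean``."""
    mean_arr = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    lam = np.empty(size, dtype=float)
    for m in np.unique(mean_arr):
        lam[mean_arr == m] = _ztp_rate(float(m))
    u = rng.uniform(size=size)
    p0 = np.exp(-lam)
    # invert the truncated CDF via the plain Poisson CDF
    draws = stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(int)
    return np.maximum(draws, 1)


def _participation_probs(
    cfg: ModeLatentConfig, respondent: np.ndarray, commune: np.ndarray, no_car: np.ndarray
) -> np.ndarray:
    intercept = np.where(
        respondent, cfg.intercept_respondent, cfg.intercept_nonrespondent
    )
    eta = (
        intercept
        + np.log(cfg.or_commune) * commune.astype(float)
        + np.log(cfg.or_no_car) * no_car.astype(float)
    )
    return _invlogit(eta)


def generate_survey(config: GeneratorConfig) -> tuple[Survey, dict]:
    """Generate a survey and its latent ground truth.

    Returns the :class:`~hotpath.survey_model.Survey` plus a ``truth``
    dict holding the per-person latent state (participation flags and
    active days per mode, response class) and the analytic expectations
    implied by the configuration — the quantities recovery tests compare
    against.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_hh, rng_pp, rng_latent, rng_trips, rng_weights = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # --- households -------------------------------------------------------
    n_hh = config.n_households
    zone = np.where(
        rng_hh.uniform(size=n_hh) < config.zone_split, "commune", "suburbaine"
    )
    car_p = np.where(
        zone == "commune",
        config.car_access["commune"],
        config.car_access["suburbaine"],
    )
    has_car = rng_hh.uniform(size=n_hh) < car_p
    n_cars = np.where(has_car, 1 + rng_hh.binomial(1, 0.35, size=n_hh), 0)
    hh_weight = rng_hh.lognormal(
        -0.5 * config.weight_log_sd**2, config.weight_log_sd, size=n_hh
    )
    households = pd.DataFrame(
        {
            "household_id": [f"H{i:06d}" for i in range(n_hh)],
            "zone": zone,
            "n_cars": n_cars,
            "weight": np.round(hh_weight, 6),
        }
    )

    # --- persons ----------------------------------------------------------
    n_per_hh = _ztp(rng_pp, config.persons_per_household_mean, n_hh)
    hh_idx = np.repeat(np.arange(n_hh), n_per_hh)
    n_pp = hh_idx.size
    p_zone = zone[hh_idx]
    p_no_car = n_cars[hh_idx] == 0
    commune = p_zone == "commune"

    sex = np.empty(n_pp, dtype=object)
    age = np.empty(n_pp, dtype=float)
    education = np.empty(n_pp, dtype=int)
    for z in ("commune", "suburbaine"):
        mask = p_zone == z
        demo = config.demographics[z]
        m = int(mask.sum())
        if m == 0:
            continue
        sex[mask] = np.where(rng_pp.uniform(size=m) < demo.sex_male_prop, "M", "F")
        a, b = (5 - demo.age_mean) / demo.age_sd, (95 - demo.age_mean) / demo.age_sd
        age[mask] = stats.truncnorm.ppf(
            rng_pp.uniform(size=m), a, b, loc=demo.age_mean, scale=demo.age_sd
        )
        education[mask] = rng_pp.choice(
            np.arange(1, 7), size=m, p=np.asarray(demo.education_probs)
        )
    age = np.round(age).astype(int)

    # --- latent travel behaviour ------------------------------------------
    respondent = rng_latent.uniform(size=n_pp) >= config.nonresponse_prob
    lt = config.latent_travel
    pi_w = _participation_probs(lt.walk, respondent, commune, p_no_car)
    pi_c = _participation_probs(lt.cycle, respondent, commune, p_no_car)

    part_w = rng_latent.uniform(size=n_pp) < pi_w
    # cycle participation conditioned on walk status so that the joint is
    # assoc * pi_w * pi_c while the cycle marginal is preserved
    kappa = lt.cycle_walk_assoc
    p_c_given_w = np.clip(kappa * pi_c, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_c_given_not_w = np.where(
            pi_w < 1.0, pi_c * (1.0 - kappa * pi_w) / (1.0 - pi_w), pi_c
        )
    p_c = np.where(part_w, p_c_given_w, np.clip(p_c_given_not_w, 0.0, 1.0))
    part_c = rng_latent.uniform(size=n_pp) < p_c

    days = {}
    for mode, part in (("walk", part_w), ("cycle", part_c)):
        cfg_m = getattr(lt, mode)
        d = np.zeros(n_pp, dtype=int)
        d[part] = rng_latent.choice(
            np.arange(1, 8), size=int(part.sum()), p=np.asarray(cfg_m.active_days_probs)
        )
        days[mode] = d

    # questionnaire answers
    answers = {}
    for mode, part in (("walk", part_w), ("cycle", part_c)):
        ans = np.full(n_pp, None, dtype=object)
        ans[respondent & part] = "week"
        idle = respondent & ~part
        ans[idle] = rng_latent.choice(
            np.array(["month", "year", "never"], dtype=object),
            size=int(idle.sum()),
            p=np.asarray(lt.nonparticipant_answer_probs),
        )
        answers[mode] = ans

    pp_weight = rng_weights.lognormal(
        -0.5 * config.weight_log_sd**2, config.weight_log_sd, size=n_pp
    )
    person_id = np.array([f"P{i:06d}" for i in range(n_pp)], dtype=object)
    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "household_id": households["household_id"].to_numpy()[hh_idx],
            "sex": sex,
            "age": age,
            "education": education,
            "walk_freq": answers["walk"],
            "cycle_freq": answers["cycle"],
            "weight": np.round(pp_weight, 6),
        }
    )

    # --- trip diary -------------------------------------------------------
    tm = config.trip_model
    trip_person: list[np.ndarray] = []
    trip_mode: list[str] = []
    for mode in ACTIVE_MODES:
        cfg_m: ActiveTripConfig = getattr(tm, mode)
        active_today = rng_trips.uniform(size=n_pp) < days[mode] / 7.0
        idx = np.flatnonzero(active_today)
        mean = cfg_m.trips_per_active_day * np.where(
            commune[idx], cfg_m.commune_trips_multiplier, 1.0
        )
        counts = _ztp(rng_trips, mean, idx.size)
        trip_person.append(np.repeat(person_id[idx], counts))
        trip_mode.extend([mode] * int(counts.sum()))
    for mode in ("car_moto", "transit", "other"):
        cfg_o: OtherTripConfig = getattr(tm, mode)
        counts = rng_trips.poisson(cfg_o.trips_per_day, size=n_pp)
        idx = np.flatnonzero(counts)
        trip_person.append(np.repeat(person_id[idx], counts[idx]))
        trip_mode.extend([mode] * int(counts[idx].sum()))

    all_person = np.concatenate(trip_person) if trip_person else np.array([], dtype=object)
    all_mode = np.array(trip_mode, dtype=object)
    durations = np.empty(all_mode.size, dtype=float)
    for mode in ("walk", "cycle", "car_moto", "transit", "other"):
        cfg_any = getattr(tm, mode)
        mask = all_mode == mode
        durations[mask] = rng_trips.lognormal(
            cfg_any.duration_log_mean, cfg_any.duration_log_sd, size=int(mask.sum())
        )
    trips = pd.DataFrame(
        {
            "trip_id": [f"T{i:07d}" for i in range(all_mode.size)],
            "person_id": all_person,
            "mode": all_mode,
            "duration_min": np.round(np.maximum(durations, 0.5), 2),
        }
    )

    survey = Survey(households=households, persons=persons, trips=trips)
    truth = {
        "config": config.model_dump(),
        "expected": expected_metrics(config),
        "latent": {
            "person_id": person_id.tolist(),
            "respondent": respondent.tolist(),
            "participant_walk": part_w.tolist(),
            "participant_cycle": part_c.tolist(),
            "active_days_walk": days["walk"].tolist(),
            "active_days_cycle": days["cycle"].tolist(),
        },
    }
    return survey, truth


def _cell_mixture(config: GeneratorConfig) -> list[tuple[float, bool, bool]]:
    """(probability, commune, no_car) cells of the covariate mixture."""
    cells = []
    for commune_flag, pz in ((True, config.zone_split), (False, 1 - config.zone_split)):
        zone = "commune" if commune_flag else "suburbaine"
        p_car = config.car_access[zone]
        for no_car_flag, pc in ((False, p_car), (True, 1 - p_car)):
            cells.append((pz * pc, commune_flag, no_car_flag))
    return cells


def expected_metrics(config: GeneratorConfig) -> dict:
    """Analytic expectations implied by a configuration.

    Returns population prevalence (overall and per mode), participation
    among questionnaire respondents (overall and per mode) and the
    frequency (mean fraction of active days among participants) per mode.
    """
    cells = _cell_mixture(config)
    lt = config.latent_travel
    f = {m: getattr(lt, m).mean_active_days() / 7.0 for m in ACTIVE_MODES}
    out: dict = {"frequency": f}

    prev_overall = 0.0
    part_resp = {m: 0.0 for m in ACTIVE_MODES}
    prev_pop = {m: 0.0 for m in ACTIVE_MODES}
    joint_resp = 0.0
    for resp, p_resp in ((True, 1 - config.nonresponse_prob), (False, config.nonresponse_prob)):
        for p_cell, commune, no_car in cells:
            w = p_resp * p_cell
            flags = np.array([resp]), np.array([commune]), np.array([no_car])
            pi_w = float(_participation_probs(lt.walk, *flags)[0])
            pi_c = float(_participation_probs(lt.cycle, *flags)[0])
            # realized joint/marginal under the sampler's conditional draw
            # (clipped where the association factor would exceed 1)
            p_cw = min(lt.cycle_walk_assoc * pi_c, 1.0)
            if pi_w < 1.0:
                p_cnw = min(
                    max(pi_c * (1.0 - lt.cycle_walk_assoc * pi_w) / (1.0 - pi_w), 0.0),
                    1.0,
                )
            else:
                p_cnw = pi_c
            pi_c_real = pi_w * p_cw + (1.0 - pi_w) * p_cnw
            joint = pi_w * p_cw
            pw, pc = pi_w * f["walk"], pi_c_real * f["cycle"]
            prev_overall += w * (pw + pc - joint * f["walk"] * f["cycle"])
            prev_pop["walk"] += w * pw
            prev_pop["cycle"] += w * pc
            if resp:
                part_resp["walk"] += p_cell * pi_w
                part_resp["cycle"] += p_cell * pi_c_real
                joint_resp += p_cell * joint
    out["prevalence_overall"] = prev_overall
    out["prevalence_by_mode"] = prev_pop
    out["participation_by_mode"] = part_resp
    out["participation_overall"] = (
        part_resp["walk"] + part_resp["cycle"] - joint_resp
    )
    return out


def write_truth(truth: dict, path: str | Path) -> None:
    """Serialise the ground-truth record to JSON (for recovery tests)."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Default configuration calibrated to the 2018 Rennes survey's headline
# figures: ~15.4% of persons in the inner city, overall one-day prevalence
# ~24.7%, overall weekly participation ~64.5% among questionnaire
# respondents (walking 62.1% / cycling 9.7%), ~54% questionnaire
# nonresponse, and inner-city / no-car participation odds in line with the
# published subgroup contrasts.
# ---------------------------------------------------------------------------

_RENNES_TARGETS = {
    "zone_split": 0.1545,
    "nonresponse": 0.54,
    "walk_participation_respondent": 0.621,
    "cycle_participation_respondent": 0.097,
    "joint_participation_respondent": 0.073,  # implies overall 0.645
    "walk_frequency": 0.461 / 0.621,
    "cycle_frequency": 0.036 / 0.097,
    "prevalence_overall": 0.247,
    "or_commune": 2.7,
    "or_no_car": 5.6,
}


def _solve_intercept(
    target: float, cells: list[tuple[float, bool, bool]], or_commune: float, or_no_car: float
) -> float:
    """Logistic intercept whose mixture-averaged participation hits *target*."""

    def marginal(b0: float) -> float:
        total = 0.0
        for p, commune, no_car in cells:
            eta = b0 + np.log(or_commune) * commune + np.log(or_no_car) * no_car
            total += p * float(_invlogit(eta))
        return total - target

    return float(optimize.brentq(marginal, -25.0, 25.0, xtol=1e-12))


def _truncated_binomial_days(target_mean: float) -> list[float]:
    """pmf over 1..7 active days: Binomial(7, q) conditioned on >= 1,
    with q solved so the truncated mean equals *target_mean*."""

    def trunc_mean(q: float) -> float:
        p0 = (1 - q) ** 7
        return 7 * q / (1 - p0) - target_mean

    q = float(optimize.brentq(trunc_mean, 1e-9, 1 - 1e-9, xtol=1e-14))
    k = np.arange(1, 8)
    pmf = stats.binom.pmf(k, 7, q) / (1 - (1 - q) ** 7)
    pmf = pmf / pmf.sum()
    return [float(p) for p in pmf]


def default_rennes_config(
    n_households: int = 8000, seed: int = 20180101
) -> GeneratorConfig:
    """Generator configuration calibrated to the 2018 Rennes survey.

    Expected overall one-day prevalence ~0.247, weekly participation among
    questionnaire respondents ~0.645 (walk 0.621, cycle 0.097), inner-city
    person share ~0.154, with zone and car-access contrasts matching the
    published subgroup pattern.  Nonrespondents to the frequency
    questionnaire carry a much lower latent participation level — the only
    configuration under which the diary and questionnaire headline figures
    are simultaneously attainable (see module docstring).
    """
    t = _RENNES_TARGETS
    probe = GeneratorConfig.model_construct(
        zone_split=t["zone_split"],
        car_access={"commune": 0.71, "suburbaine": 0.93},
    )
    cells = _cell_mixture(probe)
    log_or = (np.log(t["or_commune"]), np.log(t["or_no_car"]))

    def cell_pi(b0: float, commune: bool, no_car: bool) -> float:
        return float(_invlogit(b0 + log_or[0] * commune + log_or[1] * no_car))

    def realized_cycle(b0_w: float, b0_c: float, kappa: float) -> tuple[float, float]:
        """(marginal, joint) cycle participation over the covariate
        mixture, under the sampler's clipped conditional draw."""
        marginal = joint = 0.0
        for p_cell, commune, no_car in cells:
            pi_w = cell_pi(b0_w, commune, no_car)
            pi_c = cell_pi(b0_c, commune, no_car)
            p_cw = min(kappa * pi_c, 1.0)
            p_cnw = (
                min(max(pi_c * (1.0 - kappa * pi_w) / (1.0 - pi_w), 0.0), 1.0)
                if pi_w < 1.0
                else pi_c
            )
            marginal += p_cell * (pi_w * p_cw + (1.0 - pi_w) * p_cnw)
            joint += p_cell * pi_w * p_cw
        return marginal, joint

    # respondent class: walk intercept hits the walk target directly (walk
    # is drawn first, so its marginal is exact); the cycle intercept and
    # the association factor are solved jointly so that the realized cycle
    # marginal and the realized walk&cycle joint hit their targets, which
    # pins overall participation at walk + cycle - joint.
    walk_f, cycle_f = t["walk_frequency"], t["cycle_frequency"]
    b0_w_resp = _solve_intercept(
        t["walk_participation_respondent"], cells, t["or_commune"], t["or_no_car"]
    )
    kappa = t["joint_participation_respondent"] / (
        t["walk_participation_respondent"] * t["cycle_participation_respondent"]
    )
    b0_c_resp = 0.0
    for _ in range(12):
        b0_c_resp = float(
            optimize.brentq(
                lambda b: realized_cycle(b0_w_resp, b, kappa)[0]
                - t["cycle_participation_respondent"],
                -25.0,
                25.0,
                xtol=1e-12,
            )
        )
        kappa = float(
            optimize.brentq(
                lambda kp: realized_cycle(b0_w_resp, b0_c_resp, kp)[1]
                - t["joint_participation_respondent"],
                1e-6,
                3.0,
                xtol=1e-12,
            )
        )

    # nonrespondent class: near-inactive; the cycle level is fixed small
    # and the walk intercept is back-solved (below, on the assembled
    # config) so the population one-day prevalence hits its target.
    cycle_nonresp_part = 0.010
    b0_c_nonresp = _solve_intercept(
        cycle_nonresp_part, cells, t["or_commune"], t["or_no_car"]
    )

    def mode_cfg(b0_resp: float, b0_nonresp: float, mean_days: float) -> ModeLatentConfig:
        return ModeLatentConfig(
            intercept_respondent=b0_resp,
            intercept_nonrespondent=b0_nonresp,
            or_commune=t["or_commune"],
            or_no_car=t["or_no_car"],
            active_days_probs=_truncated_binomial_days(mean_days),
        )

    latent = LatentTravelConfig(
        walk=mode_cfg(b0_w_resp, -3.0, 7 * walk_f),
        cycle=mode_cfg(b0_c_resp, b0_c_nonresp, 7 * cycle_f),
        cycle_walk_assoc=kappa,
        nonparticipant_answer_probs=[0.2, 0.4, 0.4],
    )

    demographics = {
        # education probabilities follow the published six-category splits
        "commune": ZoneDemographics(
            sex_male_prop=0.48,
            age_mean=40.0,
            age_sd=13.0,
            education_probs=[0.013, 0.124, 0.102, 0.146, 0.159, 0.456],
        ),
        "suburbaine": ZoneDemographics(
            sex_male_prop=0.48,
            age_mean=46.0,
            age_sd=12.0,
            education_probs=[0.014, 0.177, 0.161, 0.183, 0.187, 0.278],
        ),
    }

    trip_model = TripModelConfig(
        walk=ActiveTripConfig(
            trips_per_active_day=3.0,
            commune_trips_multiplier=1.6,
            duration_log_mean=float(np.log(13.0)),
            duration_log_sd=0.55,
        ),
        cycle=ActiveTripConfig(
            trips_per_active_day=2.0,
            commune_trips_multiplier=1.6,
            duration_log_mean=float(np.log(15.0)),
            duration_log_sd=0.55,
        ),
        car_moto=OtherTripConfig(
            trips_per_day=1.65, duration_log_mean=float(np.log(15.0)), duration_log_sd=0.6
        ),
        transit=OtherTripConfig(
            trips_per_day=0.35, duration_log_mean=float(np.log(25.0)), duration_log_sd=0.5
        ),
        other=OtherTripConfig(
            trips_per_day=0.15, duration_log_mean=float(np.log(20.0)), duration_log_sd=0.6
        ),
    )

    config = GeneratorConfig(
        n_households=n_households,
        persons_per_household_mean=1.29,
        zone_split=t["zone_split"],
        demographics=demographics,
        car_access={"commune": 0.71, "suburbaine": 0.93},
        latent_travel=latent,
        trip_model=trip_model,
        nonresponse_prob=t["nonresponse"],
        weight_log_sd=0.35,
        seed=seed,
    )

    def prevalence_gap(b0: float) -> float:
        cand = config.model_copy(deep=True)
        cand.latent_travel.walk.intercept_nonrespondent = b0
        return expected_metrics(cand)["prevalence_overall"] - t["prevalence_overall"]

    b0_w_nonresp = float(optimize.brentq(prevalence_gap, -25.0, 25.0, xtol=1e-12))
    config.latent_travel.walk.intercept_nonrespondent = b0_w_nonresp
    return config
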