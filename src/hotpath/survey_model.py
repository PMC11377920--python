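"""Household travel survey data model.

A one-day household travel survey is represented as three linked tables:

``households``
    one row per household: ``household_id``, residential ``zone``
    (``commune`` = inner city, ``suburbaine`` = surrounding suburban area),
    ``n_cars`` and a survey ``weight``.
``persons``
    one row per surveyed person: demographics (sex, age, six-level
    education code), the walk/cycle frequency-questionnaire answers
    (``week``/``month``/``year``/``never``, or missing for nonresponse)
    and a person-level survey ``weight``.
``trips``
    one row per diary trip: main ``mode`` and ``duration_min`` on the
    single diary day.

The module reads and writes the three CSV files, enforces referential
integrity, and builds the person-level analysis frame used by the metric
and regression layers: adults within a configurable age band, dichotomised
education and car access, diary MET-hours per active mode, and weekly
participation indicators from the frequency questionnaire.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MODES",
    "ACTIVE_MODES",
    "FREQ_LEVELS",
    "MET_VALUES",
    "EDUCATION_LABELS",
    "HIGHLY_EDUCATED_MIN_CODE",
    "Survey",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "build_analysis_frame",
]

#: Recognised main trip modes.
MODES = ("walk", "cycle", "car_moto", "transit", "other")

#: Modes counting as active travel.
ACTIVE_MODES = ("walk", "cycle")

#: Frequency-questionnaire answer levels, most to least frequent.
FREQ_LEVELS = ("week", "month", "year", "never")

#: Metabolic equivalents assigned to active travel: walking 3 METs,
#: cycling 6 METs.
MET_VALUES = {"walk": 3.0, "cycle": 6.0}

#: Six-level education code book (French survey convention).
EDUCATION_LABELS = {
    1: "Primary School",
    2: "Secondary, from 6th to 3rd",
    3: "Secondary, beyond 2nd Without Completing Baccalaureate",
    4: "Secondary Baccalaureate",
    5: "Superior Baccalaureate, up to 2",
    6: "Superior Baccalaureate, 3+ OR Apprenticeship",
}

#: Education codes at or above this value are dichotomised as highly
#: educated (post-secondary attainment).
HIGHLY_EDUCATED_MIN_CODE = 5

_ZONES = ("commune", "suburbaine")
_SEXES = ("M", "F")


class SurveyValidationError(ValueError):
    """A survey table violates the schema or referential integrity."""


@dataclass
class Survey:
    """A validated one-day household travel survey (three linked tables)."""

    households: pd.DataFrame
    persons: pd.DataFrame
    trips: pd.DataFrame
    year: int = 2018

    def __post_init__(self) -> None:
        validate_survey(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Survey):
            return NotImplemented
        try:
            for name in ("households", "persons", "trips"):
                a = getattr(self, name).reset_index(drop=True)
                b = getattr(other, name).reset_index(drop=True)
                # normalise None vs NaN missing markers before comparing
                a = a.mask(a.isna(), np.nan)
                b = b.mask(b.isna(), np.nan)
                pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return self.year == other.year


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{table}: missing columns {missing}")


def validate_survey(survey: Survey) -> None:
    """Raise :class:`SurveyValidationError` on the first violated invariant.

    Checked: required columns, zone/sex/mode/frequency vocabularies,
    strictly positive weights and durations, and referential integrity
    (every person belongs to a household, every trip to a person).
    """
    hh, pp, tt = survey.households, survey.persons, survey.trips
    _require_columns(hh, ["household_id", "zone", "n_cars", "weight"], "households")
    _require_columns(
        pp,
        ["person_id", "household_id", "sex", "age", "education",
         "walk_freq", "cycle_freq", "weight"],
        "persons",
    )
    _require_columns(tt, ["trip_id", "person_id", "mode", "duration_min"], "trips")

    if hh["household_id"].duplicated().any():
        dup = hh.loc[hh["household_id"].duplicated(), "household_id"].iloc[0]
        raise SurveyValidationError(f"households: duplicate household_id {dup!r}")
    if pp["person_id"].duplicated().any():
        dup = pp.loc[pp["person_id"].duplicated(), "person_id"].iloc[0]
        raise SurveyValidationError(f"persons: duplicate person_id {dup!r}")

    bad_zone = ~hh["zone"].isin(_ZONES)
    if bad_zone.any():
        v = hh.loc[bad_zone, "zone"].iloc[0]
        raise SurveyValidationError(f"households: unknown zone {v!r}")
    if (hh["n_cars"] < 0).any():
        raise SurveyValidationError("households: negative n_cars")
    for table, df in (("households", hh), ("persons", pp)):
        if (df["weight"] <= 0).any():
            idx = df.index[df["weight"] <= 0][0]
            raise SurveyValidationError(f"{table}: non-positive weight at row {idx}")

    bad_sex = ~pp["sex"].isin(_SEXES)
    if bad_sex.any():
        v = pp.loc[bad_sex, "sex"].iloc[0]
        raise SurveyValidationError(f"persons: unknown sex {v!r}")
    if (~pp["education"].isin(list(EDUCATION_LABELS))).any():
        v = pp.loc[~pp["education"].isin(list(EDUCATION_LABELS)), "education"].iloc[0]
        raise SurveyValidationError(f"persons: unknown education code {v!r}")
    for col in ("walk_freq", "cycle_freq"):
        answered = pp[col].notna()
        bad = answered & ~pp[col].isin(FREQ_LEVELS)
        if bad.any():
            v = pp.loc[bad, col].iloc[0]
            raise SurveyValidationError(f"persons: unknown {col} answer {v!r}")

    orphan_p = ~pp["household_id"].isin(hh["household_id"])
    if orphan_p.any():
        pid = pp.loc[orphan_p, "person_id"].iloc[0]
        raise SurveyValidationError(f"persons: person {pid!r} references unknown household")

    bad_mode = ~tt["mode"].isin(MODES)
    if bad_mode.any():
        tid = tt.loc[bad_mode, "trip_id"].iloc[0]
        mode = tt.loc[bad_mode, "mode"].iloc[0]
        raise SurveyValidationError(f"trips: trip {tid!r} has unmapped mode {mode!r}")
    if (tt["duration_min"] <= 0).any():
        tid = tt.loc[tt["duration_min"] <= 0, "trip_id"].iloc[0]
        raise SurveyValidationError(f"trips: trip {tid!r} has non-positive duration")
    orphan_t = ~tt["person_id"].isin(pp["person_id"])
    if orphan_t.any():
        tid = tt.loc[orphan_t, "trip_id"].iloc[0]
        raise SurveyValidationError(f"trips: trip {tid!r} references unknown person")


def read_survey(directory: str | Path, year: int = 2018) -> Survey:
    """Load and validate ``households.csv``, ``persons.csv`` and
    ``trips.csv`` from *directory*.

    Missing frequency answers (empty cells or the literal ``NA``) are kept
    as missing markers — nonresponders are retained at this stage and only
    excluded from participation denominators downstream.
    """
    directory = Path(directory)
    kw = dict(keep_default_na=False, na_values=["", "NA"])
    hh = pd.read_csv(directory / "households.csv", **kw)
    pp = pd.read_csv(directory / "persons.csv", **kw)
    tt = pd.read_csv(directory / "trips.csv", **kw)
    return Survey(households=hh, persons=pp, trips=tt, year=year)


def write_survey(survey: Survey, directory: str | Path) -> None:
    """Write the three survey tables as UTF-8 CSV with header rows."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    survey.households.to_csv(directory / "households.csv", index=False)
    survey.persons.to_csv(directory / "persons.csv", index=False)
    survey.trips.to_csv(directory / "trips.csv", index=False)


def build_analysis_frame(
    survey: Survey,
    age_min: int = 18,
    age_max: int = 65,
    met_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Construct the person-level analysis frame.

    Keeps adults with ``age_min <= age <= age_max`` (both bounds
    inclusive) that are complete cases on the model covariates, and
    derives, per person:

    ``female``, ``age``, ``highly_educated``, ``no_car_access``,
    ``commune_resident``, ``weight``
        the regression covariates; education is dichotomised at
        post-secondary attainment (codes 5-6 of the six-level book) and
        car access at zero household cars.
    ``met_hours_walk`` / ``met_hours_cycle`` / ``met_hours_active``
        diary-day MET-hours per mode (duration/60 x 3 METs walking,
        6 METs cycling); walking as access/egress within a transit trip
        is not counted — only trips whose main mode is walk or cycle.
    ``active_day_walk`` / ``active_day_cycle`` / ``active_day_any``
        one or more diary trips in the mode.
    ``weekly_participant_walk`` / ``weekly_participant_cycle``
        the questionnaire answer equals ``week``; missing (NaN) when the
        question was not answered.  ``responded_walk``/``responded_cycle``
        flag whether it was answered.

    Raises ``SurveyValidationError`` if no person remains.
    """
    if met_values is None:
        met_values = MET_VALUES
    pp = survey.persons.merge(
        survey.households[["household_id", "zone", "n_cars"]],
        on="household_id",
        how="left",
    )
    keep = (
        (pp["age"] >= age_min)
        & (pp["age"] <= age_max)
        & pp["sex"].notna()
        & pp["age"].notna()
        & pp["education"].notna()
        & pp["n_cars"].notna()
        & pp["zone"].notna()
    )
    pp = pp.loc[keep].copy()
    if pp.empty:
        raise SurveyValidationError(
            f"analysis frame is empty after the age filter [{age_min}, {age_max}] "
            "and complete-case rule"
        )

    frame = pd.DataFrame(
        {
            "person_id": pp["person_id"].to_numpy(),
            "female": (pp["sex"] == "F").to_numpy(),
            "age": pp["age"].astype(float).to_numpy(),
            "highly_educated": (
                pp["education"].astype(int) >= HIGHLY_EDUCATED_MIN_CODE
            ).to_numpy(),
            "no_car_access": (pp["n_cars"].astype(int) == 0).to_numpy(),
            "commune_resident": (pp["zone"] == "commune").to_numpy(),
            "weight": pp["weight"].astype(float).to_numpy(),
        }
    )

    # diary MET-hours per active mode
    tt = survey.trips[survey.trips["mode"].isin(ACTIVE_MODES)]
    for mode in ACTIVE_MODES:
        dur = (
            tt.loc[tt["mode"] == mode]
            .groupby("person_id")["duration_min"]
            .sum()
        )
        hours = frame["person_id"].map(dur).fillna(0.0) / 60.0
        frame[f"met_hours_{mode}"] = hours * met_values[mode]
        frame[f"active_day_{mode}"] = frame["person_id"].map(dur).notna().to_numpy()
    frame["met_hours_active"] = frame["met_hours_walk"] + frame["met_hours_cycle"]
    frame["active_day_any"] = frame["active_day_walk"] | frame["active_day_cycle"]

    for mode in ACTIVE_MODES:
        ans = pp[f"{mode}_freq"]
        frame[f"responded_{mode}"] = ans.notna().to_numpy()
        part = pd.Series(np.where(ans.notna(), ans == "week", np.nan), dtype=float)
        frame[f"weekly_participant_{mode}"] = part.to_numpy()
    return frame.reset_index(drop=True)
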