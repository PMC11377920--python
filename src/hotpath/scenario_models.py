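"""Policy scenario models for active-travel activity change.

Two complementary models translate a transport policy into a per-person
change in weekly travel activity, ``delta_TA`` (MET-hours/week), using
3 METs for walking and 6 METs for cycling.

Travel Time Substitution (TTS)
    A fraction ``alpha`` of the mean weekly time spent in non-active
    modes, ``t_o`` minutes, is replaced by active travel, split between
    walking (share ``gamma_w``) and cycling::

        delta_TA = alpha * t_o / 60 * (6 - 3 * gamma_w)

    ``gamma_w`` defaults to the population's current walking share of
    active-travel time, ``t_w / (t_w + t_c)``.  This represents e.g. a
    10% reduction in vehicle miles traveled as ``alpha = 0.10`` of
    other-mode travel time.

Mode Share Shift (MSS)
    Walk and cycle trip shares increase by ``delta_w`` and ``delta_c``
    (other modes absorb the difference; the total number of trips is held
    constant).  With ``N`` weekly trips per person and median trip
    durations ``t_w``, ``t_c`` minutes::

        delta_TA = N / 60 * (3 * t_w * delta_w + 6 * t_c * delta_c)

Both are linear in their policy levers, and they agree in the matched
special case where the substituted time equals the added trip time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "MET_WALK",
    "MET_CYCLE",
    "TtsSpec",
    "MssSpec",
    "ActivityChange",
    "tts_delta_ta",
    "mss_delta_ta",
    "mode_share_to_trip_deltas",
    "activity_to_weekly_minutes",
]

MET_WALK = 3.0
MET_CYCLE = 6.0


class TtsSpec(BaseModel):
    """Inputs of the Travel Time Substitution model (minutes are mean
    weekly minutes per person)."""

    model_config = ConfigDict(extra="forbid")

    t_w: float = Field(ge=0.0, description="weekly walking minutes")
    t_c: float = Field(ge=0.0, description="weekly cycling minutes")
    t_o: float = Field(ge=0.0, description="weekly minutes in other modes")
    alpha_replaced: float = Field(ge=0.0, le=1.0, description="fraction of t_o replaced")
    gamma_w: float | None = Field(
        default=None, ge=0.0, le=1.0, description="walk share of the replaced time"
    )

    @model_validator(mode="after")
    def _check_gamma_default(self) -> "TtsSpec":
        if self.gamma_w is None and self.t_w + self.t_c == 0:
            raise ValueError(
                "gamma_w cannot default to t_w/(t_w+t_c) when t_w + t_c = 0"
            )
        return self

    @property
    def walk_share(self) -> float:
        if self.gamma_w is not None:
            return self.gamma_w
        return self.t_w / (self.t_w + self.t_c)


class MssSpec(BaseModel):
    """Inputs of the Mode Share Shift model."""

    model_config = ConfigDict(extra="forbid")

    n_weekly_trips: float = Field(gt=0.0, description="mean weekly trips per person")
    t_med_w: float = Field(gt=0.0, description="median walk trip duration, minutes")
    t_med_c: float = Field(gt=0.0, description="median cycle trip duration, minutes")
    delta_w: float = Field(description="walk mode-share increment")
    delta_c: float = Field(description="cycle mode-share increment")
    #: baseline shares (walk, cycle, other); used to validate that the
    #: shifted shares stay in [0, 1]
    baseline_shares: tuple[float, float, float] | None = None

    @model_validator(mode="after")
    def _check_shares(self) -> "MssSpec":
        if self.baseline_shares is not None:
            s_w, s_c, s_o = self.baseline_shares
            if abs(s_w + s_c + s_o - 1.0) > 1e-9:
                raise ValueError("baseline_shares must sum to 1")
            shifted = (
                s_w + self.delta_w,
                s_c + self.delta_c,
                s_o - self.delta_w - self.delta_c,
            )
            if any(s < -1e-12 or s > 1 + 1e-12 for s in shifted):
                raise ValueError(
                    f"shifted mode shares {shifted} leave the interval [0, 1]"
                )
        return self


@dataclass(frozen=True)
class ActivityChange:
    """A per-person change in weekly travel activity, MET-hours/week."""

    delta_ta: float
    model: str  # 'tts' or 'mss'
    inputs: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_ta):
            raise ValueError("delta_ta must be finite")


def tts_delta_ta(spec: TtsSpec) -> ActivityChange:
    """Travel Time Substitution:
    ``delta_TA = alpha * t_o/60 * (6 - 3*gamma_w)``."""
    gamma = spec.walk_share
    delta = spec.alpha_replaced * spec.t_o / 60.0 * (MET_CYCLE - MET_WALK * gamma)
    return ActivityChange(delta_ta=delta, model="tts", inputs=spec.model_dump())


def mss_delta_ta(spec: MssSpec) -> ActivityChange:
    """Mode Share Shift:
    ``delta_TA = N/60 * (3*t_w*delta_w + 6*t_c*delta_c)``."""
    delta = (
        spec.n_weekly_trips
        / 60.0
        * (MET_WALK * spec.t_med_w * spec.delta_w + MET_CYCLE * spec.t_med_c * spec.delta_c)
    )
    return ActivityChange(delta_ta=delta, model="mss", inputs=spec.model_dump())


def mode_share_to_trip_deltas(
    baseline_daily_trips_by_mode: Mapping[str, float],
    target_shares: Mapping[str, float],
) -> dict[str, float]:
    """Daily trips added/removed per mode to reach *target_shares* while
    holding the total number of trips constant.

    ``delta_m = (target_share_m - baseline_share_m) * total_daily_trips``;
    the deltas sum to zero by construction.
    """
    modes = list(baseline_daily_trips_by_mode)
    if set(target_shares) != set(modes):
        raise ValueError("target_shares must cover exactly the baseline modes")
    baseline = np.array([baseline_daily_trips_by_mode[m] for m in modes], dtype=float)
    target = np.array([target_shares[m] for m in modes], dtype=float)
    total = baseline.sum()
    if total <= 0:
        raise ValueError("baseline trips must be positive")
    if (target < 0).any():
        raise ValueError("target shares must be non-negative")
    if abs(target.sum() - 1.0) > 1e-9:
        raise ValueError(f"target shares sum to {target.sum():.12f}, not 1")
    deltas = (target - baseline / total) * total
    return dict(zip(modes, (float(d) for d in deltas)))


def activity_to_weekly_minutes(delta_ta: float, met_value: float) -> float:
    """Weekly minutes of a single mode equivalent to *delta_ta*
    MET-hours/week at *met_value* METs (e.g. 3.91 MET-h/wk is ~39 min of
    cycling at 6 METs)."""
    if met_value <= 0:
        raise ValueError("met_value must be positive")
    return delta_ta / met_value * 60.0
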