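"""Subgroup association tests and multivariate regressions.

Three models mirror the descriptive metrics:

* prevalence — weighted logistic regression of the one-day active
  indicator on sex, age, education, car access and inner-city residency
  (odds ratios);
* participation — the same logistic model for the weekly questionnaire
  indicator, fitted on questionnaire respondents;
* intensity — log-linear (least squares on log weekly MET-hours) among
  weekly participants with positive activity, coefficients reported as
  proportional changes in log-intensity.

Survey weights enter as weighted estimating equations with robust
(sandwich) standard errors by default; an unweighted option reproduces
the textbook fits exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .hot_metrics import kish_n_eff

__all__ = [
    "DEFAULT_COVARIATES",
    "RegressionResult",
    "PerfectSeparationError",
    "weighted_chisq",
    "fit_logistic",
    "fit_loglinear_intensity",
]

DEFAULT_COVARIATES = ("female", "age", "highly_educated", "no_car_access", "commune_resident")

class PerfectSeparationError(RuntimeError):
    """The logistic likelihood is unbounded: a covariate separates the outcome."""


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    estimate: float  # odds ratio (logistic) or log-intensity change (log-linear)
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    model: str  # 'logistic' or 'loglinear'
    effects: list[CovariateEffect]
    n: int
    weighted: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outcome": self.outcome,
                "covariate": [e.name for e in self.effects],
                "estimate": [e.estimate for e in self.effects],
                "ci_low": [e.ci_low for e in self.effects],
                "ci_high": [e.ci_high for e in self.effects],
                "p_value": [e.p_value for e in self.effects],
            }
        )

    def effect(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def weighted_chisq(
    frame: pd.DataFrame,
    factor: str,
    outcome: str,
    weight_col: str = "weight",
) -> tuple[float, float]:
    """Weighted chi-squared test of association between two categorical
    columns.

    The weighted contingency table is rescaled so its total equals the
    Kish effective sample size, then the ordinary Pearson statistic (no
    continuity correction) is referred to chi-squared((r-1)(c-1)).
    Returns ``(statistic, p_value)``.
    """
    w = frame[weight_col].to_numpy(dtype=float)
    table = pd.crosstab(
        frame[factor], frame[outcome], values=w, aggfunc="sum"
    ).fillna(0.0)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("factor and outcome need at least 2 levels each")
    obs = table.to_numpy()
    n_eff = kish_n_eff(w)
    obs = obs / obs.sum() * n_eff
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected == 0).any():
        raise ValueError("zero expected cell count")
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p_value = float(stats.chi2.sf(statistic, df))
    return statistic, p_value


def _design(frame: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    X = frame[list(covariates)].astype(float)
    return sm.add_constant(X, has_constant="add")


def _outcome_vector(frame: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, np.ndarray]:
    if outcome == "prevalence":
        return frame, frame["active_day_any"].to_numpy(dtype=float)
    if outcome == "participation":
        resp = (frame["responded_walk"] | frame["responded_cycle"]).to_numpy()
        sub = frame.loc[resp]
        y = (
            (sub["weekly_participant_walk"] == 1.0)
            | (sub["weekly_participant_cycle"] == 1.0)
        ).to_numpy(dtype=float)
        return sub, y
    raise ValueError(f"unknown outcome {outcome!r}; expected 'prevalence' or 'participation'")


def fit_logistic(
    frame: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    weighted: bool = True,
) -> RegressionResult:
    """Weighted maximum-likelihood logistic regression.

    Effects are reported as odds ratios with Wald 95% confidence
    intervals on the exponentiated scale.  Weights are normalised to mean
    one and used as frequency weights in the estimating equations, with
    HC1 sandwich covariance; ``weighted=False`` gives the plain fit.
    """
    sub, y = _outcome_vector(frame, outcome)
    X = _design(sub, covariates)
    if y.min() == y.max():
        raise PerfectSeparationError("outcome is constant in this frame")
    for cov in covariates:
        x = sub[cov].astype(float)
        if x.nunique() <= 1:
            continue
        lo, hi = y[x <= x.median()], y[x > x.median()]
        if (lo.size and hi.size) and (
            (lo.max() == 0 and hi.min() == 1) or (lo.min() == 1 and hi.max() == 0)
        ):
            raise PerfectSeparationError(
                f"covariate {cov!r} perfectly separates the outcome; remove it"
            )
    if weighted:
        w = sub["weight"].to_numpy(dtype=float)
        w = w / w.mean()
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        fit = model.fit(cov_type="HC1")
    else:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    conf = fit.conf_int()
    effects = []
    for cov in covariates:
        effects.append(
            CovariateEffect(
                name=cov,
                estimate=float(np.exp(fit.params[cov])),
                ci_low=float(np.exp(conf.loc[cov, 0])),
                ci_high=float(np.exp(conf.loc[cov, 1])),
                p_value=float(fit.pvalues[cov]),
            )
        )
    return RegressionResult(
        outcome=outcome, model="logistic", effects=effects, n=len(sub), weighted=weighted
    )


def fit_loglinear_intensity(
    frame: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    f_by_mode: dict[str, float] | None = None,
    weighted: bool = True,
) -> RegressionResult:
    """Log-linear regression of weekly active-travel MET-hours.

    Restricted to weekly participants (either questionnaire indicator)
    with positive weekly activity; the response is
    ``log(sum_m diary_MET_hours_m x 7 x f_m)``.  Coefficients are
    proportional changes in log-intensity with Wald 95% intervals.
    """
    if f_by_mode is None:
        f_by_mode = {"walk": 1.0, "cycle": 1.0}
    part = (
        (frame["weekly_participant_walk"] == 1.0)
        | (frame["weekly_participant_cycle"] == 1.0)
    ).to_numpy()
    sub = frame.loc[part].copy()
    weekly = (
        sub["met_hours_walk"].to_numpy() * 7.0 * min(f_by_mode["walk"], 1.0)
        + sub["met_hours_cycle"].to_numpy() * 7.0 * min(f_by_mode["cycle"], 1.0)
    )
    positive = weekly > 0
    sub = sub.loc[positive]
    weekly = weekly[positive]
    if sub.empty:
        raise ValueError("no weekly participants with positive weekly MET-hours")
    X = _design(sub, covariates)
    y = np.log(weekly)
    if weighted:
        w = sub["weight"].to_numpy(dtype=float)
        w = w / w.mean()
        fit = sm.WLS(y, X, weights=w).fit(cov_type="HC1")
    else:
        fit = sm.OLS(y, X).fit()
    conf = fit.conf_int()
    effects = [
        CovariateEffect(
            name=cov,
            estimate=float(fit.params[cov]),
            ci_low=float(conf.loc[cov, 0]),
            ci_high=float(conf.loc[cov, 1]),
            p_value=float(fit.pvalues[cov]),
        )
        for cov in covariates
    ]
    return RegressionResult(
        outcome="intensity", model="loglinear", effects=effects, n=len(sub), weighted=weighted
    )
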