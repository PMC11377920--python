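"""Pipeline orchestration and report rendering.

Runs the full analysis from a single configuration: survey input (CSV
directory or synthetic generator), HOT metrics, subgroup regressions,
policy scenarios, and health/economic impacts.  Outputs are written to
one directory as machine-readable JSON plus rendered CSV tables (and a
mode-share bar chart); every number in a rendered table is taken from
the corresponding JSON value, and a manifest records the seed, package
version and configuration hash so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .survey_model import ACTIVE_MODES, FREQ_LEVELS, EDUCATION_LABELS, Survey, build_analysis_frame, read_survey, write_survey
from .synthetic_survey import (
    GeneratorConfig,
    default_rennes_config,
    generate_survey,
    write_truth,
)
from .hot_metrics import compute_hot_summary, mode_share
from .subgroup_inference import fit_logistic, fit_loglinear_intensity
from .scenario_models import (
    MssSpec,
    TtsSpec,
    mss_delta_ta,
    tts_delta_ta,
)
from .health_impact import (
    BurdenInputs,
    CostModel,
    DAROUDI_COST,
    ExposureResponse,
    RENNES_BASELINE_ACTIVITY,
    RENNES_ERF,
    assess_impact,
)

__all__ = ["PipelineConfig", "ScenarioConfig", "run_pipeline", "scenario_inputs_from_frame"]

logger = logging.getLogger("hotpath")

ALL_STAGES = ("metrics", "regress", "scenario", "impact", "report")


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    type: Literal["tts", "mss"]
    #: model parameters (TtsSpec or MssSpec fields); parameters omitted
    #: here are derived from the survey when ``from_survey`` is true
    parameters: dict[str, Any] = Field(default_factory=dict)
    from_survey: bool = False


class PipelineConfig(BaseModel):
    """One configuration drives the whole pipeline; exactly one of
    ``input_dir`` (CSV survey) or ``generator`` (synthetic survey) must be
    present, and all randomness flows from ``seed``."""

    model_config = ConfigDict(extra="forbid")

    input_dir: str | None = None
    generator: GeneratorConfig | None = None
    #: named generator configuration, as a YAML-friendly alternative to
    #: spelling out a full generator block
    generator_preset: Literal["rennes-2018"] | None = None
    preset_n_households: int = 8000
    age_min: int = 18
    age_max: int = 65
    weighted: bool = True
    scenarios: list[ScenarioConfig] = Field(default_factory=list)
    burden: dict[str, float] | None = None
    cost: dict[str, float] | None = None
    erf: dict[str, float] | None = None
    baseline_activity: float = RENNES_BASELINE_ACTIVITY
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        n_sources = sum(
            x is not None for x in (self.input_dir, self.generator, self.generator_preset)
        )
        if n_sources != 1:
            raise ValueError(
                "exactly one of input_dir, generator or generator_preset must be set"
            )
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def scenario_inputs_from_frame(
    survey: Survey, frame: pd.DataFrame
) -> dict[str, float]:
    """Derive scenario-model inputs from the survey.

    Weekly per-person minutes by mode group (``t_w``, ``t_c``, ``t_o`` =
    7 x mean daily minutes over analysis-frame persons), mean weekly
    trips ``n_weekly_trips``, and median walk/cycle trip durations.
    """
    ids = set(frame["person_id"])
    tt = survey.trips[survey.trips["person_id"].isin(ids)]
    n = len(frame)
    daily_minutes = {m: 0.0 for m in ("walk", "cycle", "other")}
    for mode, grp in tt.groupby("mode"):
        key = mode if mode in ACTIVE_MODES else "other"
        daily_minutes[key] += float(grp["duration_min"].sum()) / n
    med = {
        m: float(tt.loc[tt["mode"] == m, "duration_min"].median())
        for m in ACTIVE_MODES
        if (tt["mode"] == m).any()
    }
    return {
        "t_w": 7.0 * daily_minutes["walk"],
        "t_c": 7.0 * daily_minutes["cycle"],
        "t_o": 7.0 * daily_minutes["other"],
        "n_weekly_trips": 7.0 * len(tt) / n,
        "t_med_w": med.get("walk", float("nan")),
        "t_med_c": med.get("cycle", float("nan")),
    }


def _scenario_delta(
    sc: ScenarioConfig, derived: dict[str, float]
) -> tuple[float, dict[str, Any]]:
    params = dict(sc.parameters)
    if sc.from_survey:
        fields = (
            ("t_w", "t_c", "t_o") if sc.type == "tts"
            else ("n_weekly_trips", "t_med_w", "t_med_c")
        )
        for f in fields:
            params.setdefault(f, derived[f])
    if sc.type == "tts":
        change = tts_delta_ta(TtsSpec(**params))
    else:
        change = mss_delta_ta(MssSpec(**params))
    return change.delta_ta, change.inputs


def _characteristics_table(survey: Survey, frame: pd.DataFrame) -> pd.DataFrame:
    """Participant characteristics split by residential zone."""
    pp = survey.persons.merge(
        survey.households[["household_id", "zone", "n_cars"]], on="household_id"
    )
    pp = pp[pp["person_id"].isin(set(frame["person_id"]))]
    rows = []

    def add(characteristic: str, level: str, fn) -> None:
        row: dict[str, Any] = {"characteristic": characteristic, "level": level}
        for zone in ("commune", "suburbaine"):
            row[zone] = fn(pp[pp["zone"] == zone])
        rows.append(row)

    add("N", "", lambda d: len(d))
    for sex in ("M", "F"):
        add("sex", sex, lambda d, s=sex: f"{(d['sex'] == s).sum()} ({(d['sex'] == s).mean():.0%})")
    add("age", "mean (sd)", lambda d: f"{d['age'].mean():.0f} ({d['age'].std():.0f})")
    for code, label in EDUCATION_LABELS.items():
        add(
            "education",
            label,
            lambda d, c=code: f"{(d['education'] == c).sum()} ({(d['education'] == c).mean():.1%})",
        )
    for level, label in (("yes", "Yes"), ("no", "No")):
        add(
            "car access",
            label,
            lambda d, lv=level: (
                f"{((d['n_cars'] > 0) == (lv == 'yes')).sum()} "
                f"({((d['n_cars'] > 0) == (lv == 'yes')).mean():.0%})"
            ),
        )
    for mode in ACTIVE_MODES:
        col = f"{mode}_freq"
        answered = pp[pp[col].notna()]
        for level in FREQ_LEVELS:
            add(
                f"{mode} frequency",
                level,
                lambda d, lv=level, c=col: (
                    f"{(d[c] == lv).sum()} "
                    f"({((d[c] == lv).sum() / max(d[c].notna().sum(), 1)):.1%})"
                ),
            )
    return pd.DataFrame(rows)


def _mode_share_chart(shares: pd.Series, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    shares.plot.bar(ax=ax, color="#4878a8")
    ax.set_ylabel("share of diary trips")
    ax.set_title("Mode share")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES
) -> dict[str, Any]:
    """Run the requested pipeline stages and write the report bundle.

    Outputs (depending on stages): ``metrics.json``, ``table1.csv``,
    ``table2.csv``, ``table3.csv``, ``impact.json``, ``modeshare.png``
    and always ``manifest.json``.  Returns the bundle as a dict.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if "impact" in stages and config.scenarios and config.burden is None:
        # fail before any computation, per the pipeline contract
        raise ValueError("impact stage requested but no burden inputs configured")

    if config.generator is not None or config.generator_preset is not None:
        if config.generator is not None:
            gen = config.generator.model_copy(update={"seed": config.seed})
        else:
            gen = default_rennes_config(
                n_households=config.preset_n_households, seed=config.seed
            )
        logger.info("generating synthetic survey (seed=%d)", config.seed)
        survey, truth = generate_survey(gen)
        write_survey(survey, out_dir / "survey")
        write_truth(truth, out_dir / "survey" / "truth.json")
    else:
        logger.info("reading survey from %s", config.input_dir)
        survey = read_survey(config.input_dir)
    frame = build_analysis_frame(survey, config.age_min, config.age_max)
    bundle: dict[str, Any] = {}

    if "metrics" in stages:
        summary = compute_hot_summary(frame)
        bundle["metrics"] = summary.to_dict()
        _json_dump(bundle["metrics"], out_dir / "metrics.json")

    if "regress" in stages:
        results = [
            fit_logistic(frame, "prevalence", weighted=config.weighted),
            fit_logistic(frame, "participation", weighted=config.weighted),
            fit_loglinear_intensity(frame, weighted=config.weighted),
        ]
        table2 = pd.concat([r.to_frame() for r in results], ignore_index=True)
        table2.to_csv(out_dir / "table2.csv", index=False)
        bundle["regressions"] = table2.to_dict(orient="records")

    derived = scenario_inputs_from_frame(survey, frame)
    if "scenario" in stages or "impact" in stages:
        scenario_rows = []
        for sc in config.scenarios:
            delta, inputs = _scenario_delta(sc, derived)
            scenario_rows.append(
                {"name": sc.name, "type": sc.type, "delta_ta": delta, "inputs": inputs}
            )
        bundle["scenarios"] = scenario_rows

    if "impact" in stages and config.scenarios:
        erf = (
            ExposureResponse(**config.erf) if config.erf is not None else RENNES_ERF
        )
        burden = BurdenInputs(**config.burden)
        cost = CostModel(**config.cost) if config.cost is not None else DAROUDI_COST
        impact_rows = []
        for row in bundle["scenarios"]:
            impact = assess_impact(
                row["delta_ta"],
                x_b=config.baseline_activity,
                erf=erf,
                burden=burden,
                cost=cost,
            )
            impact_rows.append(
                {
                    "scenario": row["name"],
                    "delta_ta": row["delta_ta"],
                    "rho": impact.rho,
                    "averted_deaths": impact.averted_deaths,
                    "averted_dalys": impact.averted_dalys,
                    "cost_million_usd_central": impact.cost_saved_central / 1e6,
                    "cost_million_usd_low": impact.cost_saved_low / 1e6,
                    "cost_million_usd_high": impact.cost_saved_high / 1e6,
                }
            )
        bundle["impacts"] = impact_rows
        _json_dump(impact_rows, out_dir / "impact.json")
        # rendered table mirrors the JSON with presentation rounding
        table3 = pd.DataFrame(
            [
                {
                    "scenario": r["scenario"],
                    "delta_ta_met_h_week": round(r["delta_ta"], 2),
                    "averted_deaths": round(r["averted_deaths"]),
                    "averted_dalys": round(r["averted_dalys"]),
                    "cost_million_usd": round(r["cost_million_usd_central"]),
                    "cost_million_usd_low": round(r["cost_million_usd_low"]),
                    "cost_million_usd_high": round(r["cost_million_usd_high"]),
                }
                for r in impact_rows
            ]
        )
        table3.to_csv(out_dir / "table3.csv", index=False)

    if "report" in stages:
        table1 = _characteristics_table(survey, frame)
        table1.to_csv(out_dir / "table1.csv", index=False)
        weights = survey.persons.set_index("person_id")["weight"]
        shares = mode_share(survey.trips, weights)
        bundle["mode_share"] = {k: float(v) for k, v in shares.items()}
        _mode_share_chart(shares, out_dir / "modeshare.png")

    # hash the analytic configuration only (not output location / verbosity)
    config_json = json.dumps(
        config.model_dump(exclude={"out_dir", "log_level"}), sort_keys=True, default=float
    )
    manifest = {
        "package": "hotpath",
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_persons": int(len(survey.persons)),
        "n_frame": int(len(frame)),
    }
    _json_dump(manifest, out_dir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
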