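"""End-to-end orchestration: generate/load -> validate -> score ->
regress -> calibrate -> fsQCA, with reproducible file artifacts.

A run is driven by a single :class:`RunConfig` (serializable as YAML) and
writes UTF-8 CSV artifacts plus a machine-readable manifest into an output
directory.  Re-running with the same config and seed reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, scales
from .calibration import CalibrationSpec, calibrate_dataset, percentile_anchors
from .errors import ConfigError, DataError
from .qca import Expectation, FsqcaReport, configuration_chart, run_fsqca
from .regression import RegressionTable, backward_eliminate

# the eight configurational conditions
CONDITIONS = [
    "age",
    "marital",
    "education",
    "exercise",
    "occupational_stress",
    "self_rated_health",
    "sleep_hours",
    "ssrs_total",
]

# theory-guided directional expectations for the intermediate solution:
# protective conditions expected present, stress expected absent, age and
# exercise left open
DEFAULT_EXPECTATIONS: dict[str, Expectation] = {
    "age": "either",
    "marital": "present",
    "education": "present",
    "exercise": "either",
    "occupational_stress": "absent",
    "self_rated_health": "present",
    "sleep_hours": "present",
    "ssrs_total": "present",
}

REGRESSION_PREDICTORS = [
    "age",
    "register",
    "marital",
    "education",
    "income",
    "self_rated_health",
    "two_week_illness",
    "chronic",
    "smoke",
    "drink",
    "exercise",
    "occupational_stress",
    "sleep_hours",
    "ssrs_level",
]

# declared reference levels for categorical predictors
REGRESSION_CATEGORICAL: dict[str, object] = {
    "register": 0,
    "marital": 0,
    "education": 1,
    "income": 1,
    "self_rated_health": 1,
    "two_week_illness": 1,
    "chronic": 0,
    "smoke": 0,
    "drink": 0,
    "exercise": 1,
    "occupational_stress": 1,
    "ssrs_level": "low",
}

REQUIRED_COLUMNS = (
    ["age", "register", "marital", "education", "income", "self_rated_health",
     "two_week_illness", "chronic", "smoke", "drink", "exercise",
     "occupational_stress", "sleep_hours"]
    + scales.CESD_COLS + scales.GAD_COLS
    + scales.SSRS_LIKERT_COLS + scales.SSRS_ITEM5_COLS + scales.SSRS_SOURCE_COLS
)

Outcome = Literal["non_depression", "non_anxiety"]

# survey-scale defaults: frequency 10; consistency 0.80, raised to 0.85 for
# the depression outcome to sharpen the configuration set
DEFAULT_FREQ_THRESHOLD = 10
DEFAULT_CONS_THRESHOLDS: dict[str, float] = {"non_depression": 0.85, "non_anxiety": 0.80}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_csv: str | None = None  # exactly one of input_csv / synthetic
    synthetic: cohort.CohortConfig | None = None
    outcomes: tuple[Outcome, ...] = ("non_depression", "non_anxiety")
    freq_threshold: int = DEFAULT_FREQ_THRESHOLD
    cons_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONS_THRESHOLDS)
    )
    expectations: dict[str, Expectation] = field(
        default_factory=lambda: dict(DEFAULT_EXPECTATIONS)
    )
    removal_alpha: float = 0.10
    output_dir: str = "results/run"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_csv / synthetic must be set")
        if self.freq_threshold < 1:
            raise ConfigError("freq_threshold must be >= 1")
        for oc in self.outcomes:
            if oc not in ("non_depression", "non_anxiety"):
                raise ConfigError(f"unknown outcome {oc!r}")
            thr = self.cons_thresholds.get(oc)
            if thr is None or not 0 < thr <= 1:
                raise ConfigError(f"consistency threshold for {oc!r} must be in (0, 1]")
        if self.synthetic is not None:
            self.synthetic.validate()


@dataclass
class ValidationReport:
    n_distributed: int
    n_valid: int
    n_invalid: int
    response_rate: float  # percent

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_input(table: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Drop rows with any missing required field; report the accounting.

    The response rate is valid/distributed as a percentage (e.g. 3,063 of
    3,298 -> 92.87%).
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise DataError(f"input table lacks required columns: {', '.join(missing_cols[:5])} ...")
    n_distributed = len(table)
    valid_mask = table[REQUIRED_COLUMNS].notna().all(axis=1)
    valid = table.loc[valid_mask].copy()
    n_valid = len(valid)
    if n_valid == 0:
        raise DataError("no valid rows after removing records with missing data")
    report = ValidationReport(
        n_distributed, n_valid, n_distributed - n_valid,
        round(100.0 * n_valid / n_distributed, 2),
    )
    return valid, report


def default_calibration_specs(scored: pd.DataFrame) -> list[CalibrationSpec]:
    """Calibration scheme for the eight conditions.

    Continuous conditions take percentile anchors from their own
    distribution (90/50/10; 85/50/15 for the right-skewed age and sleep),
    occupational stress anchors the crossover at its sample mean,
    five-point Likert conditions use anchors 5/3/1, education the
    six-value fuzzy set, and marital status passes through as crisp.
    """
    age_a = percentile_anchors(scored["age"], 85, 50, 15)
    sleep_a = percentile_anchors(scored["sleep_hours"], 85, 50, 15)
    ssrs_a = percentile_anchors(scored["ssrs_total"], 90, 50, 10)
    stress_mean = float(scored["occupational_stress"].mean())
    return [
        CalibrationSpec("age", "direct", *age_a),
        CalibrationSpec("marital", "binary"),
        CalibrationSpec("education", "indirect6"),
        CalibrationSpec("exercise", "likert5"),
        CalibrationSpec("occupational_stress", "direct", 5, stress_mean, 1),
        CalibrationSpec("self_rated_health", "likert5"),
        CalibrationSpec("sleep_hours", "direct", *sleep_a),
        CalibrationSpec("ssrs_total", "direct", *ssrs_a),
    ]


@dataclass
class RunResult:
    config: RunConfig
    validation: ValidationReport
    scored: pd.DataFrame
    regressions: dict[str, RegressionTable]
    reports: dict[str, FsqcaReport]
    output_dir: Path


def _necessity_frame(report: FsqcaReport) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.condition, r.consistency, r.coverage, r.necessary) for r in report.necessity],
        columns=["condition", "consistency", "coverage", "necessary"],
    )


def _configuration_frame(report: FsqcaReport) -> pd.DataFrame:
    rows = []
    for kind in ("complex", "parsimonious", "intermediate"):
        sol = getattr(report, kind)
        for i, cfg in enumerate(sol.configurations, start=1):
            row = {"solution": kind, "configuration": i}
            for name in report.condition_names:
                row[name] = cfg.roles.get(name, "")
            row.update(
                consistency=cfg.consistency,
                raw_coverage=cfg.raw_coverage,
                unique_coverage=cfg.unique_coverage,
                solution_consistency=sol.solution_consistency,
                solution_coverage=sol.solution_coverage,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write artifacts under output_dir."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        raw = cohort.generate_cohort(syn)
        raw.to_csv(outdir / "cohort.csv", index=False)
    else:
        try:
            raw = pd.read_csv(config.input_csv)
        except OSError as exc:
            raise DataError(f"cannot read input CSV {config.input_csv!r}: {exc}") from exc

    valid, report = validate_input(raw)
    scored = scales.score_cohort(valid)
    scored.to_csv(outdir / "scored.csv", index=False)

    regressions: dict[str, RegressionTable] = {}
    for oc in config.outcomes:
        ycol = "depression_positive" if oc == "non_depression" else "anxiety_positive"
        reg = backward_eliminate(
            scored, ycol, REGRESSION_PREDICTORS, REGRESSION_CATEGORICAL,
            removal_alpha=config.removal_alpha,
        )
        reg.table.to_csv(outdir / f"regression_{oc}.csv", index=False)
        regressions[oc] = reg

    specs = default_calibration_specs(scored)
    reports: dict[str, FsqcaReport] = {}
    for oc in config.outcomes:
        fds = calibrate_dataset(scored, specs, oc, case_id_col="case_id")
        rep = run_fsqca(
            fds,
            freq_threshold=config.freq_threshold,
            cons_threshold=config.cons_thresholds[oc],
            expectations=config.expectations,
        )
        _necessity_frame(rep).to_csv(outdir / f"necessity_{oc}.csv", index=False)
        _configuration_frame(rep).to_csv(outdir / f"configurations_{oc}.csv", index=False)
        (outdir / f"chart_{oc}.txt").write_text(
            configuration_chart(rep.intermediate, rep.condition_names) + "\n",
            encoding="utf-8",
        )
        reports[oc] = rep

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "validation": report.as_dict(),
        "config": _config_to_dict(config),
        "calibration_anchors": {
            s.variable: {"method": s.method, "full_in": s.full_in,
                         "crossover": s.crossover, "full_out": s.full_out}
            for s in specs
        },
    }
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
    )
    return RunResult(config, report, scored, regressions, reports, outdir)


def _config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("synthetic") is not None:
        d["synthetic"]["planted_recipes"] = [
            {**{"conditions": dict(r["conditions"])},
             **{k: r[k] for k in ("outcome", "p_match", "p_else")}}
            for r in d["synthetic"]["planted_recipes"]
        ]
    d["outcomes"] = list(d["outcomes"])
    return d


def config_from_dict(d: Mapping) -> RunConfig:
    d = dict(d)
    syn = d.get("synthetic")
    if syn is not None:
        syn = dict(syn)
        recipes = [
            cohort.PlantedRecipe(
                conditions=dict(r["conditions"]),
                outcome=r.get("outcome", "non_depression"),
                p_match=r.get("p_match", 0.99),
                p_else=r.get("p_else", 0.70),
            )
            for r in syn.pop("planted_recipes", [])
        ]
        coeffs = syn.pop("coefficients", None)
        cc = cohort.CohortConfig(**syn)
        if coeffs is not None:
            cc.coefficients = {k: tuple(v) for k, v in coeffs.items()}
        cc.planted_recipes = recipes
        d["synthetic"] = cc
    if "outcomes" in d:
        d["outcomes"] = tuple(d["outcomes"])
    return RunConfig(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))
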