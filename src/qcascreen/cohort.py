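"""Seeded synthetic survey-cohort generator.

Emulates a cross-sectional women's mental-health screening survey: one row
per respondent with sociodemographics, lifestyle, health status and
item-level responses for the CESD-10, GAD-7 and SSRS instruments.

Generative model
----------------
Categorical and continuous covariates are drawn independently from
configured marginal distributions (defaults reproduce the published
frequency table of the survey this package models: e.g. 63.8% married,
mean age 34.7 +/- 11.1 years).  Age uses a left-truncated skew-normal
(adults only, positively skewed); sleep a normal rounded to half hours.

Mental health is driven by two correlated standard-normal latent distress
factors (depressive and anxious distress).  Each factor is a linear
combination of standardized covariates plus a noise term; the two noise
terms share a correlation ``rho``, which produces depression-anxiety
comorbidity over and above the shared covariates.  Scale items are
generated by cumulative-threshold discretization of the respondent's
latent factor plus independent item noise, so that scale totals correlate
with the planted condition effects.  Item thresholds are calibrated so
that the default cohort reproduces the screening prevalences the design
targets (about 16.7% depression-positive, 26.0% anxiety-positive, and
about two-thirds of depression-positives also anxiety-positive).

Planted recipes
---------------
For engine-recovery experiments a cohort can be built from explicit
condition-combination -> outcome-propensity rules: respondents whose
conditions all sit on the recipe's side of the calibration crossovers
screen healthy with high probability, everyone else at a baseline, so the
recipe surfaces downstream as a high-consistency truth-table row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import scales
from .calibration import CalibrationSpec, direct_calibrate, indirect6_calibrate
from .errors import ConfigError

# ---------------------------------------------------------------------------
# default marginal structure (normalized published frequencies)

CATEGORICAL_LEVELS: dict[str, list[int]] = {
    "register": [0, 1],  # 0 rural, 1 urban
    "marital": [0, 1],  # 0 not married, 1 married
    "education": [1, 2, 3, 4, 5, 6],  # primary-and-below ... postgraduate
    "income": [1, 2, 3, 4, 5, 6],  # annual household income bands, low to high
    "self_rated_health": [1, 2, 3, 4, 5],  # 1 very poor ... 5 excellent
    "two_week_illness": [1, 2, 3, 4],  # 1 sought care, 2 self-medicated, 3 bed rest, 4 none
    "chronic": [0, 1],
    "smoke": [0, 1],
    "drink": [0, 1],
    "exercise": [1, 2, 3, 4, 5],  # 1 never ... 5 every day
    "occupational_stress": [1, 2, 3, 4, 5],  # 1 very low ... 5 very high
}

_RAW_DEFAULT_PROBS: dict[str, list[float]] = {
    "register": [0.388, 0.612],
    "marital": [0.362, 0.638],
    "education": [0.010, 0.076, 0.106, 0.212, 0.446, 0.151],
    "income": [0.195, 0.137, 0.141, 0.183, 0.236, 0.108],
    "self_rated_health": [0.004, 0.034, 0.406, 0.415, 0.141],
    "two_week_illness": [0.056, 0.084, 0.023, 0.838],
    "chronic": [0.824, 0.176],
    "smoke": [0.968, 0.032],
    "drink": [0.613, 0.387],
    "exercise": [0.059, 0.481, 0.333, 0.111, 0.016],
    "occupational_stress": [0.058, 0.058, 0.542, 0.267, 0.075],
}

DEFAULT_MARGINALS: dict[str, list[float]] = {
    k: (np.array(v) / np.sum(v)).tolist() for k, v in _RAW_DEFAULT_PROBS.items()
}

# age: left-truncated (>= 18) skew-normal; parameters solved numerically so the
# truncated distribution has mean 34.7 and sd 11.1 with 15/50/85 percentiles
# near 23/33/47 (younger-skewed adult cohort)
AGE_SKEW = 4.0
AGE_LOC = 19.625
AGE_SCALE = 18.298
AGE_MIN = 18.0

SLEEP_MEAN = 7.3
SLEEP_SD = 1.0
SLEEP_LO, SLEEP_HI = 4.0, 11.0

# SSRS measurement model: one support latent, 12 Likert components (items
# 1-4, five parts of item 5, items 8-10) discretized at common cutpoints,
# plus source counts for items 6-7
SSRS_LOADING = 0.63  # sqrt of latent variance share per component
SSRS_CUTS = (-1.48, -0.84, -0.10)  # z-scale cutpoints -> categories 1..4
SSRS_SOURCE_INTERCEPT = -1.1  # binomial(9) logit intercept for items 6-7
SSRS_SOURCE_SLOPE = 0.55

# distress measurement models (calibrated to the target screening prevalences:
# ~16.7% depression-positive, ~26.0% anxiety-positive, ~67% comorbidity)
CESD_LOADING = 0.70
CESD_CUTS = (0.47, 1.31, 2.11)
GAD_LOADING = 0.74
GAD_CUTS = (0.49, 1.40, 2.28)
DEFAULT_RHO = 0.68

# standardization constants for covariates entering the latent model (fixed,
# not re-estimated per cohort, so effects are stable across sample sizes)
_FEATURE_STATS = {
    "age": (34.7, 11.1),
    "marital": (0.638, 0.48),
    "education": (4.46, 1.15),
    "exercise": (2.54, 0.82),
    "occupational_stress": (3.24, 0.90),
    "self_rated_health": (3.66, 0.80),
    "sleep_hours": (7.3, 1.0),
    "ssrs_total": (40.9, 7.0),
    "smoke": (0.032, 0.176),
    "drink": (0.387, 0.487),
    "chronic": (0.176, 0.381),
    "illness_none": (0.838, 0.369),
}

# condition -> latent-distress coefficients (depression, anxiety); signs
# follow the protective/risk directions the survey literature reports
DEFAULT_COEFFS: dict[str, tuple[float, float]] = {
    "age": (-0.08, -0.08),
    "marital": (-0.14, -0.12),
    "education": (-0.10, -0.08),
    "exercise": (-0.06, -0.09),
    "occupational_stress": (0.22, 0.24),
    "self_rated_health": (-0.30, -0.26),
    "sleep_hours": (-0.12, -0.14),
    "ssrs_total": (-0.28, -0.22),
    "smoke": (0.10, 0.04),
    "drink": (0.03, 0.07),
    "chronic": (0.05, 0.09),
    "illness_none": (-0.12, -0.14),
}


@dataclass(frozen=True)
class PlantedRecipe:
    """A condition-combination -> outcome-propensity rule.

    ``conditions`` maps condition names (raw cohort columns among the eight
    configurational conditions) to "present"/"absent".  A respondent
    matches the recipe when every named condition sits on the stated side
    of its calibration crossover (membership >= 0.5) — the same rule that
    later assigns cases to truth-table corners.  Matching respondents
    screen healthy on ``outcome`` with probability ``p_match``, everyone
    else with the baseline ``p_else``.
    """

    conditions: Mapping[str, Literal["present", "absent"]]
    outcome: Literal["non_depression", "non_anxiety"] = "non_depression"
    p_match: float = 0.99
    p_else: float = 0.70

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("planted recipe needs at least one condition")
        for c, state in self.conditions.items():
            if state not in ("present", "absent"):
                raise ConfigError(f"recipe condition {c!r}: state must be present/absent")
        for name, p in (("p_match", self.p_match), ("p_else", self.p_else)):
            if not 0 <= p <= 1:
                raise ConfigError(f"recipe {name} outside [0, 1]")


@dataclass
class CohortConfig:
    """Configuration for one synthetic cohort draw."""

    n_respondents: int = 3063
    seed: int = 0
    marginals: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    coefficients: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COEFFS)
    )
    rho: float = DEFAULT_RHO
    planted_recipes: list[PlantedRecipe] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_respondents < 1:
            raise ConfigError("n_respondents must be >= 1 (empty cohort disallowed)")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho {self.rho} outside [-1, 1]")
        for var, probs in self.marginals.items():
            if var not in CATEGORICAL_LEVELS:
                raise ConfigError(f"unknown marginal variable {var!r}")
            p = np.asarray(probs, dtype=float)
            if len(p) != len(CATEGORICAL_LEVELS[var]):
                raise ConfigError(
                    f"marginal for {var!r}: {len(p)} probabilities for "
                    f"{len(CATEGORICAL_LEVELS[var])} levels"
                )
            if (p < 0).any():
                raise ConfigError(f"marginal for {var!r}: negative probability")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"marginal for {var!r}: probabilities sum to {p.sum()}, not 1")


# fixed raw-scale anchors used for recipe membership (the same substantive
# anchors the default pipeline calibration targets)
_RECIPE_SPECS: dict[str, CalibrationSpec] = {
    "age": CalibrationSpec("age", "direct", 47, 33, 23),
    "sleep_hours": CalibrationSpec("sleep_hours", "direct", 8, 7, 6),
    "ssrs_total": CalibrationSpec("ssrs_total", "direct", 49, 41, 31),
    "occupational_stress": CalibrationSpec("occupational_stress", "direct", 5, 3.24, 1),
    "self_rated_health": CalibrationSpec("self_rated_health", "likert5"),
    "exercise": CalibrationSpec("exercise", "likert5"),
}


def _recipe_match(recipe: PlantedRecipe, df: pd.DataFrame) -> np.ndarray:
    """Crisp per-case recipe match: every literal membership >= 0.5."""
    sides = []
    for cond, state in recipe.conditions.items():
        if cond == "marital":
            m = df["marital"].to_numpy(dtype=float)
        elif cond == "education":
            m = indirect6_calibrate(df["education"].to_numpy())
        elif cond in _RECIPE_SPECS:
            m = direct_calibrate(df[cond].to_numpy(dtype=float), _RECIPE_SPECS[cond])
        else:
            raise ConfigError(f"recipe condition {cond!r} is not a recognised fsQCA condition")
        if state == "absent":
            m = 1.0 - m
        sides.append(m >= 0.5)
    return np.logical_and.reduce(sides)


def _ordinal_items(
    latent: np.ndarray, n_items: int, loading: float, cuts: Sequence[float],
    rng: np.random.Generator, base: int,
) -> np.ndarray:
    """Cumulative-threshold discretization of latent + independent item noise."""
    n = latent.shape[0]
    noise = rng.standard_normal((n, n_items))
    z = loading * latent[:, None] + np.sqrt(1.0 - loading**2) * noise
    out = np.zeros((n, n_items), dtype=int)
    for c in cuts:
        out += z > c
    return out + base


def _truncated_skewnorm(rng: np.random.Generator, n: int) -> np.ndarray:
    dist = stats.skewnorm(AGE_SKEW, loc=AGE_LOC, scale=AGE_SCALE)
    lo = dist.cdf(AGE_MIN)
    u = rng.uniform(lo, 1.0, size=n)
    return dist.ppf(u)


def _standardize(df: pd.DataFrame) -> dict[str, np.ndarray]:
    feats = {}
    for name, (mu, sd) in _FEATURE_STATS.items():
        if name == "illness_none":
            raw = (df["two_week_illness"] == 4).astype(float).to_numpy()
        else:
            raw = df[name].to_numpy(dtype=float)
        feats[name] = (raw - mu) / sd
    return feats


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table; identical config (incl. seed) -> identical table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    df = pd.DataFrame({"case_id": np.arange(1, n + 1)})

    for var, levels in CATEGORICAL_LEVELS.items():
        probs = np.asarray(config.marginals[var], dtype=float)
        df[var] = rng.choice(levels, size=n, p=probs)

    df["age"] = np.round(_truncated_skewnorm(rng, n), 1)
    sleep = np.round(rng.normal(SLEEP_MEAN, SLEEP_SD, size=n) * 2.0) / 2.0
    df["sleep_hours"] = np.clip(sleep, SLEEP_LO, SLEEP_HI)

    # social support: latent + 12 Likert components + two source-count items
    support_latent = rng.standard_normal(n)
    comp = _ordinal_items(support_latent, 12, SSRS_LOADING, SSRS_CUTS, rng, base=1)
    likert_cols = scales.SSRS_LIKERT_COLS + scales.SSRS_ITEM5_COLS
    for i, col in enumerate(likert_cols):
        df[col] = comp[:, i]
    p_src = 1.0 / (1.0 + np.exp(-(SSRS_SOURCE_INTERCEPT + SSRS_SOURCE_SLOPE * support_latent)))
    df["ssrs_6"] = rng.binomial(9, p_src)
    df["ssrs_7"] = rng.binomial(9, p_src)
    df["ssrs_total"] = comp.sum(axis=1) + (df["ssrs_6"] > 0) + (df["ssrs_7"] > 0)

    # latent distress: covariate effects + correlated noise
    feats = _standardize(df)
    mu_dep = np.zeros(n)
    mu_anx = np.zeros(n)
    for name, (b_dep, b_anx) in config.coefficients.items():
        if name not in feats:
            raise ConfigError(f"latent-model coefficient for unknown feature {name!r}")
        mu_dep += b_dep * feats[name]
        mu_anx += b_anx * feats[name]
    cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
    noise = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    latent_dep = mu_dep + noise[:, 0]
    latent_anx = mu_anx + noise[:, 1]

    if config.planted_recipes:
        latent_dep, latent_anx = _apply_recipes(
            config, df, latent_dep, latent_anx, rng
        )

    cesd = _ordinal_items(latent_dep, 10, CESD_LOADING, CESD_CUTS, rng, base=0)
    gad = _ordinal_items(latent_anx, 7, GAD_LOADING, GAD_CUTS, rng, base=0)
    for i, col in enumerate(scales.CESD_COLS):
        df[col] = cesd[:, i]
    for i, col in enumerate(scales.GAD_COLS):
        df[col] = gad[:, i]

    df = df.drop(columns=["ssrs_total"])  # recomputed downstream by scale scoring
    return df


# latent levels producing near-deterministic screen outcomes (healthy / positive)
_PLANT_LATENT = {"healthy": -1.6, "positive": 2.6}


def _apply_recipes(
    config: CohortConfig,
    df: pd.DataFrame,
    latent_dep: np.ndarray,
    latent_anx: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Override the latent factors targeted by planted recipes.

    The targeted factor is replaced by a well-separated two-level latent so
    the screening outcome is essentially Bernoulli in the recipe
    propensity; the untouched factor keeps its covariate-driven value.
    """
    n = len(df)
    for recipe in config.planted_recipes:
        match = _recipe_match(recipe, df)
        p_healthy = np.where(match, recipe.p_match, recipe.p_else)
        healthy = rng.uniform(size=n) < p_healthy
        jitter = 0.35 * rng.standard_normal(n)
        planted = np.where(
            healthy, _PLANT_LATENT["healthy"], _PLANT_LATENT["positive"]
        ) + jitter
        if recipe.outcome == "non_depression":
            latent_dep = planted
        else:
            latent_anx = planted
    return latent_dep, latent_anx


def marginal_report(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-variable empirical frequencies; mean +/- sd for continuous."""
    from .errors import DataError

    if len(cohort) == 0:
        raise DataError("marginal_report: empty cohort")
    report: dict[str, pd.DataFrame] = {}
    for var, levels in CATEGORICAL_LEVELS.items():
        freq = cohort[var].value_counts(normalize=True).reindex(levels, fill_value=0.0)
        report[var] = pd.DataFrame({"level": levels, "frequency": freq.to_numpy()})
    for var in ("age", "sleep_hours"):
        report[var] = pd.DataFrame(
            {"mean": [cohort[var].mean()], "sd": [cohort[var].std(ddof=1)]}
        )
    return report
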