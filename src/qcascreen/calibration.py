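"""Fuzzy-set calibration: raw survey variables -> set memberships in [0, 1].

The direct method maps three substantive anchors (full membership,
crossover, full non-membership) onto log-odds +3 / 0 / -3 and passes raw
values through a piecewise-linear log-odds transform followed by the
logistic function.  Anchored values therefore land at memberships of about
0.953, 0.5 and 0.047, and interpolation handles asymmetric anchor spacing
(e.g. sleep anchors 6/7/8 hours vs age anchors 23/33/47 years).

Ordered five-point Likert variables are calibrated directly with anchors
(5, 3, 1); a six-level ordered variable (education) is calibrated
indirectly onto the equal-spaced six-value fuzzy set {0, 0.2, ..., 1};
binary variables pass through unchanged.

Because a membership of exactly 0.5 belongs to no truth-table row, a small
constant (0.001) is added to any calibrated score equal to 0.5 before
set-theoretic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

LOGODDS_AT_ANCHOR = 3.0  # log-odds assigned to the full-membership anchors
HALF_ADJUST = 0.001

Method = Literal["direct", "likert5", "binary", "indirect6", "negate"]
Direction = Literal["higher_is_member", "lower_is_member"]


@dataclass(frozen=True)
class CalibrationSpec:
    """Anchors and method for one variable.

    For ``method='direct'`` the three anchors are on the raw scale;
    ``direction`` states whether larger raw values indicate fuller
    membership.  The other methods ignore the anchors.
    """

    variable: str
    method: Method = "direct"
    full_in: float | None = None
    crossover: float | None = None
    full_out: float | None = None
    direction: Direction = "higher_is_member"

    def __post_init__(self) -> None:
        if self.method == "likert5":
            anchors = (5.0, 3.0, 1.0) if self.direction == "higher_is_member" else (1.0, 3.0, 5.0)
            object.__setattr__(self, "full_in", anchors[0])
            object.__setattr__(self, "crossover", anchors[1])
            object.__setattr__(self, "full_out", anchors[2])
        if self.method in ("direct", "likert5"):
            fi, xo, fo = self.full_in, self.crossover, self.full_out
            if fi is None or xo is None or fo is None:
                raise ConfigError(f"{self.variable}: direct calibration needs all three anchors")
            if not all(np.isfinite([fi, xo, fo])):
                raise ConfigError(f"{self.variable}: anchors must be finite")
            if self.direction == "higher_is_member":
                ok = fo < xo < fi
            else:
                ok = fi < xo < fo
            if not ok:
                raise ConfigError(
                    f"{self.variable}: anchors not strictly monotone for direction "
                    f"{self.direction}: full_in={fi}, crossover={xo}, full_out={fo}"
                )


def percentile_anchors(
    values: Sequence[float], p_in: float, p_mid: float, p_out: float
) -> tuple[float, float, float]:
    """Empirical-percentile anchors (full_in, crossover, full_out).

    Percentiles use linear interpolation between order statistics (the
    numpy/R default, "type 7"), fixed here for reproducibility.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("percentile_anchors: empty vector")
    for p in (p_in, p_mid, p_out):
        if not 0 < p < 100:
            raise ConfigError(f"percentile {p} outside (0, 100)")
    fi, xo, fo = np.percentile(arr, [p_in, p_mid, p_out])
    if fi == xo or xo == fo:
        raise ValidationError(
            "percentile_anchors: anchors coincide "
            f"({fi}, {xo}, {fo}); variable cannot be calibrated directly"
        )
    return float(fi), float(xo), float(fo)


def _logodds(x: np.ndarray, spec: CalibrationSpec) -> np.ndarray:
    """Piecewise-linear raw -> log-odds map through the three anchors."""
    fi, xo, fo = float(spec.full_in), float(spec.crossover), float(spec.full_out)
    upper_slope = LOGODDS_AT_ANCHOR / (fi - xo)
    lower_slope = LOGODDS_AT_ANCHOR / (xo - fo)
    above = (x - xo) >= 0 if spec.direction == "higher_is_member" else (x - xo) <= 0
    return np.where(above, (x - xo) * upper_slope, (x - xo) * lower_slope)


def direct_calibrate(x, spec: CalibrationSpec):
    """Direct-method membership of raw value(s) ``x`` under ``spec``.

    Anchors map to memberships exp(3)/(1+exp(3)) ~ 0.953, 0.5 and ~ 0.047;
    values beyond the outer anchors continue along the same log-odds slope,
    so memberships approach 0/1 asymptotically.  Monotone in ``x``.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{spec.variable}: non-finite raw value")
    m = 1.0 / (1.0 + np.exp(-_logodds(arr, spec)))
    return float(m) if np.isscalar(x) else m


def likert5_calibrate(x, direction: Direction = "higher_is_member"):
    """Five-point Likert calibration with anchors 5 / 3 / 1 (or reversed)."""
    arr = np.asarray(x)
    if not np.isin(arr, [1, 2, 3, 4, 5]).all():
        raise ValidationError(f"likert5: value outside 1..5: {x!r}")
    spec = CalibrationSpec("likert5", method="likert5", direction=direction)
    return direct_calibrate(x, spec)


INDIRECT6_GRID = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


def indirect6_calibrate(level):
    """Six ordered levels onto the equal-spaced six-value set {0,.2,...,1}."""
    arr = np.asarray(level)
    if not np.isin(arr, [1, 2, 3, 4, 5, 6]).all():
        raise ValidationError(f"indirect6: level outside 1..6: {level!r}")
    m = INDIRECT6_GRID[np.asarray(arr, dtype=int) - 1]
    return float(m) if np.isscalar(level) else m


def binary_calibrate(x):
    """Identity on {0, 1}: crisp variables need no calibration."""
    arr = np.asarray(x)
    if not np.isin(arr, [0, 1]).all():
        raise ValidationError(f"binary_calibrate: value outside {{0,1}}: {x!r}")
    m = np.asarray(arr, dtype=float)
    return float(m) if np.isscalar(x) else m


def adjust_half(memberships, eps: float = 1e-12):
    """Nudge memberships of exactly 0.5 up by 0.001; leave the rest alone."""
    arr = np.asarray(memberships, dtype=float)
    out = np.where(np.abs(arr - 0.5) <= eps, 0.5 + HALF_ADJUST, arr)
    return float(out) if np.isscalar(memberships) else out


@dataclass
class FuzzyDataset:
    """Cases x conditions membership matrix plus outcome memberships."""

    case_ids: np.ndarray
    condition_names: list[str]
    memberships: np.ndarray  # shape (n_cases, n_conditions), in [0, 1]
    outcome: np.ndarray  # shape (n_cases,), in [0, 1]
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        n, k = self.memberships.shape
        if len(self.condition_names) != k:
            raise ConfigError("condition_names length mismatch with matrix")
        if self.outcome.shape != (n,):
            raise ConfigError("outcome length mismatch with matrix")
        for name, a in (("memberships", self.memberships), ("outcome", self.outcome)):
            if ((a < 0) | (a > 1)).any():
                raise ValidationError(f"{name} outside [0, 1]")

    @property
    def n_cases(self) -> int:
        return self.memberships.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.memberships.shape[1]

    def negate_conditions(self) -> "FuzzyDataset":
        """Complement all condition sets (1 - m).

        Negation is exactly involutive: negating twice restores the
        original membership matrix bit for bit (a second float subtraction
        could lose a ulp, so the source matrix is reused instead).
        """
        source = getattr(self, "_negated_from", None)
        mat = source if source is not None else 1.0 - self.memberships
        out = FuzzyDataset(
            self.case_ids, list(self.condition_names), mat,
            self.outcome, self.outcome_name,
        )
        if source is None:
            out._negated_from = self.memberships.copy()  # type: ignore[attr-defined]
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.memberships, columns=self.condition_names)
        df.insert(0, "case_id", self.case_ids)
        df[self.outcome_name] = self.outcome
        return df


def _apply_spec(values: np.ndarray, spec: CalibrationSpec) -> np.ndarray:
    if spec.method in ("direct", "likert5"):
        return direct_calibrate(values, spec)
    if spec.method == "binary":
        return binary_calibrate(values)
    if spec.method == "indirect6":
        return indirect6_calibrate(values)
    if spec.method == "negate":
        return 1.0 - binary_calibrate(values)
    raise ConfigError(f"{spec.variable}: unknown calibration method {spec.method!r}")


def calibrate_dataset(
    scored: pd.DataFrame,
    specs: Sequence[CalibrationSpec],
    outcome: Literal["non_depression", "non_anxiety"],
    case_id_col: str | None = None,
) -> FuzzyDataset:
    """Calibrate a scored cohort into a FuzzyDataset for one outcome.

    The outcome set is "screens negative": membership 1 for respondents
    without the symptom (fully psychologically healthy on that scale) and 0
    for screen-positives.  Condition columns are calibrated per spec and
    then half-point adjusted so no case sits on a truth-table boundary.
    """
    outcome_col = {"non_depression": "depression_positive", "non_anxiety": "anxiety_positive"}
    if outcome not in outcome_col:
        raise ConfigError(f"unknown outcome {outcome!r}")
    col = outcome_col[outcome]
    if col not in scored.columns:
        raise ConfigError(f"scored cohort lacks column {col!r}; run scale scoring first")
    cols_missing = [s.variable for s in specs if s.variable not in scored.columns]
    if cols_missing:
        raise ConfigError(f"no data column for condition(s): {', '.join(cols_missing)}")

    mat = np.column_stack(
        [adjust_half(_apply_spec(scored[s.variable].to_numpy(), s)) for s in specs]
    )
    y = 1.0 - scored[col].to_numpy(dtype=float)
    ids = scored[case_id_col].to_numpy() if case_id_col else np.arange(len(scored))
    return FuzzyDataset(ids, [s.variable for s in specs], mat, y, outcome_name=outcome)
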