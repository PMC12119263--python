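"""Binary logistic regression with backward elimination, plus the
scale-score correlation and the cross-sectional sample-size formula.

Models are maximum-likelihood logistic fits (statsmodels); odds ratios are
reported with Wald 95% confidence intervals exp(beta +/- 1.96 SE), the
presentation conventional for survey epidemiology.  Backward elimination
removes, at each step, the predictor whose likelihood-ratio test against
the current model has the largest p-value above the removal threshold
(default 0.10), refitting until every remaining predictor passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError, DataError

Z95 = stats.norm.ppf(0.975)


@dataclass
class RegressionTable:
    """Per-level odds ratios with Wald CIs plus elimination metadata."""

    table: pd.DataFrame  # variable, level, estimate, odds_ratio, ci_low, ci_high, p_value, reference
    predictors: list[str]
    eliminated: list[str] = field(default_factory=list)
    llf: float = float("nan")
    n_obs: int = 0
    _model: object = None  # fitted statsmodels results, for LR tests


def _design_matrix(
    data: pd.DataFrame,
    predictors: Sequence[str],
    categorical: Mapping[str, object],
) -> tuple[pd.DataFrame, list[tuple[str, object, str, bool]]]:
    """Expanded design columns plus (variable, level, column, is_reference) rows."""
    cols: dict[str, np.ndarray] = {}
    layout: list[tuple[str, object, str, bool]] = []
    for var in predictors:
        if var not in data.columns:
            raise ConfigError(f"predictor {var!r} not in data")
        if var in categorical:
            ref = categorical[var]
            levels = sorted(data[var].unique().tolist())
            if ref not in levels:
                raise ConfigError(f"reference level {ref!r} absent from predictor {var!r}")
            for lev in levels:
                n_lev = int((data[var] == lev).sum())
                if n_lev == 0:
                    raise DataError(f"empty level {lev!r} in predictor {var!r}")
                if lev == ref:
                    layout.append((var, lev, "", True))
                else:
                    col = f"{var}[{lev}]"
                    cols[col] = (data[var] == lev).to_numpy(dtype=float)
                    layout.append((var, lev, col, False))
        else:
            col = var
            cols[col] = data[var].to_numpy(dtype=float)
            layout.append((var, "", col, False))
    return pd.DataFrame(cols, index=data.index), layout


def _fit(outcome: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(outcome, Xc)
    try:
        res = model.fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"singular design matrix: {exc}") from exc
    except Exception as exc:  # statsmodels PerfectSeparationError
        if "erfect" in type(exc).__name__ or "erfect" in str(exc):
            raise DataError(f"perfect separation in design: {exc}") from exc
        raise
    big = [c for c, b in res.params.items() if c != "const" and abs(b) > 15]
    if big:
        raise DataError(f"perfect (or quasi-perfect) separation on predictor(s): {', '.join(big)}")
    return res


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    categorical: Mapping[str, object] | None = None,
) -> RegressionTable:
    """Fit a binary logistic model and tabulate ORs with 95% Wald CIs.

    ``categorical`` maps predictor names to their declared reference
    level; other predictors enter as numeric.  Reference rows appear in
    the table flagged, with no estimate.
    """
    categorical = dict(categorical or {})
    y = data[outcome].to_numpy()
    if not np.isin(y, [0, 1]).all():
        raise DataError(f"outcome {outcome!r} is not binary 0/1")
    X, layout = _design_matrix(data, predictors, categorical)
    res = _fit(y, X)
    rows = []
    for var, lev, col, is_ref in layout:
        if is_ref:
            rows.append((var, lev, np.nan, np.nan, np.nan, np.nan, np.nan, True))
        else:
            b = res.params[col]
            se = res.bse[col]
            rows.append((
                var, lev, b, math.exp(b),
                math.exp(b - Z95 * se), math.exp(b + Z95 * se),
                res.pvalues[col], False,
            ))
    table = pd.DataFrame(
        rows,
        columns=["variable", "level", "estimate", "odds_ratio", "ci_low", "ci_high", "p_value", "reference"],
    )
    out = RegressionTable(table, list(predictors), [], float(res.llf), int(res.nobs))
    out._model = res
    out._data = data  # type: ignore[attr-defined]
    out._outcome = outcome  # type: ignore[attr-defined]
    out._categorical = categorical  # type: ignore[attr-defined]
    return out


def _lr_pvalue(full: RegressionTable, drop: str) -> float:
    """Likelihood-ratio p-value for removing one predictor (all its levels)."""
    data = full._data  # type: ignore[attr-defined]
    reduced_preds = [p for p in full.predictors if p != drop]
    y = data[full._outcome].to_numpy()  # type: ignore[attr-defined]
    cat = {k: v for k, v in full._categorical.items() if k != drop}  # type: ignore[attr-defined]
    X, _ = _design_matrix(data, reduced_preds, cat)
    res = _fit(y, X)
    lr = 2.0 * (full.llf - res.llf)
    df = full._model.df_model - res.df_model  # type: ignore[union-attr]
    return float(stats.chi2.sf(max(lr, 0.0), max(int(df), 1)))


def backward_eliminate(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    categorical: Mapping[str, object] | None = None,
    removal_alpha: float = 0.10,
) -> RegressionTable:
    """Backward elimination by likelihood-ratio tests.

    Repeatedly drops the predictor with the largest LR p-value above
    ``removal_alpha``; an empty final model is reported as intercept-only.
    The elimination order is logged on the result.
    """
    if not 0 < removal_alpha <= 1:
        raise ConfigError("removal_alpha must be in (0, 1]")
    current = list(predictors)
    eliminated: list[str] = []
    while current:
        fit = fit_logistic(data, outcome, current, categorical)
        pvals = {p: _lr_pvalue(fit, p) for p in current}
        worst, worst_p = max(pvals.items(), key=lambda kv: kv[1])
        if worst_p <= removal_alpha:
            fit.eliminated = eliminated
            return fit
        current.remove(worst)
        eliminated.append(worst)
    # intercept-only final model
    empty = RegressionTable(
        pd.DataFrame(
            columns=["variable", "level", "estimate", "odds_ratio", "ci_low", "ci_high", "p_value", "reference"]
        ),
        [], eliminated, float("nan"), len(data),
    )
    return empty


def spearman_scores(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("spearman_scores: unequal lengths")
    if x.size < 3:
        raise DataError("spearman_scores: need n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DataError("spearman_scores: constant vector, correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class SampleSize:
    base: float  # z^2 p (1-p) / E^2
    design_adjusted: float  # base * DEFF
    final: int  # ceil(design_adjusted * (1 + inflation))


def sample_size(
    p: float, E: float, z: float = 1.96, deff: float = 1.0, inflation: float = 0.0
) -> SampleSize:
    """Cross-sectional prevalence-survey sample size, staged.

    base = z^2 p(1-p)/E^2, inflated by the design effect for multi-stage
    sampling and then by an anticipated-loss proportion (ceiling).
    """
    if not 0 < p < 1:
        raise ConfigError("p must be in (0, 1)")
    if E <= 0:
        raise ConfigError("margin of error E must be > 0")
    if deff < 1:
        raise ConfigError("design effect must be >= 1")
    if inflation < 0:
        raise ConfigError("inflation must be >= 0")
    base = z**2 * p * (1 - p) / E**2
    adjusted = base * deff
    final = math.ceil(adjusted * (1 + inflation))
    return SampleSize(base, adjusted, final)
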