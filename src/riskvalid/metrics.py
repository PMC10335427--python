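"""Discrimination, overall and calibration performance of risk predictions.

Discrimination is the AUC (concordance probability, ties credited 0.5) with
a DeLong variance; overall performance is the Brier score.  Calibration is
summarised three ways:

* expected/observed (E/O) ratio — sum of predicted risks over the event
  count; values below 1 mean the model underpredicts;
* calibration-in-the-large (CITL) — the intercept of a logistic regression
  of the outcome on the linear predictor entered as a fixed offset; 0 means
  predictions are on-average right on the log-odds scale;
* calibration slope — the coefficient of the linear predictor in a free
  logistic refit; 1 means the weights are correctly scaled.

Grouped calibration-plot data use equal-size risk groups (default 10) with
Wilson confidence intervals on the observed proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class MetricError(ValueError):
    pass


def _check_binary(outcomes: np.ndarray) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise MetricError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise MetricError("both outcome classes must be present")
    return y.astype(int)


@dataclass(frozen=True)
class DiscriminationReport:
    auc: float
    auc_variance: float
    brier: float


@dataclass(frozen=True)
class CalibrationReport:
    expected: float
    observed: int
    eo_ratio: float
    citl: float
    citl_variance: float
    slope: float
    slope_variance: float


@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    lower: float
    upper: float
    method: str = "wilson"


@dataclass(frozen=True)
class CalibrationPlotData:
    """Per-group (mean predicted risk, observed proportion, Wilson CI, size)."""

    mean_predicted: np.ndarray
    observed_proportion: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    group_size: np.ndarray
    group_count: int


def auc(probabilities, outcomes) -> tuple[float, float]:
    """Concordance probability and its DeLong variance.

    Midrank formulation: identical to exhaustive case-control pair counting
    with ties credited 0.5, at O(n log n).
    """
    y = _check_binary(outcomes)
    p = np.asarray(probabilities, dtype=float)
    cases = p[y == 1]
    controls = p[y == 0]
    m, n = len(cases), len(controls)

    all_ranks = _midrank(np.concatenate([cases, controls]))
    case_ranks = _midrank(cases)
    control_ranks = _midrank(controls)
    auc_hat = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - case_ranks) / n          # per-case placement values
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m  # per-control
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    variance = s10 / m + s01 / n
    return float(auc_hat), float(variance)


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based) with ties averaged."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j < len(sx) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1.0
        i = j
    return ranks


def brier(probabilities, outcomes) -> float:
    """Mean squared difference between predicted risk and outcome."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise MetricError("probabilities must lie in [0,1]")
    y = np.asarray(outcomes, dtype=float)
    return float(np.mean((p - y) ** 2))


def discrimination(probabilities, outcomes) -> DiscriminationReport:
    a, v = auc(probabilities, outcomes)
    return DiscriminationReport(auc=a, auc_variance=v, brier=brier(probabilities, outcomes))


def _offset_intercept_fit(y: np.ndarray, eta: np.ndarray) -> tuple[float, float]:
    """Intercept (and its variance) of logit(P(y=1)) = delta + offset eta."""
    X = np.ones((len(y), 1))
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial(), offset=eta).fit()
        return float(fit.params[0]), float(fit.bse[0] ** 2)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        warnings.warn("separation in offset fit; falling back to penalised fit")
        fit = sm.GLM(y, X, family=sm.families.Binomial(), offset=eta).fit_regularized(
            alpha=1e-4, L1_wt=0.0
        )
        return float(fit.params[0]), float("nan")


def _slope_fit(y: np.ndarray, eta: np.ndarray) -> tuple[float, float, float]:
    """(intercept, slope, slope variance) of a free logistic refit on eta."""
    X = sm.add_constant(np.asarray(eta, dtype=float))
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return float(fit.params[0]), float(fit.params[1]), float(fit.bse[1] ** 2)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        warnings.warn("separation in slope fit; falling back to penalised fit")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-4, L1_wt=0.0
        )
        return float(fit.params[0]), float(fit.params[1]), float("nan")


def calibration(linear_predictors, outcomes) -> CalibrationReport:
    """E/O ratio, CITL and calibration slope for linear predictors eta."""
    y = _check_binary(outcomes)
    eta = np.asarray(linear_predictors, dtype=float)
    expected = float(expit(eta).sum())
    observed = int(y.sum())
    citl, citl_var = _offset_intercept_fit(y, eta)
    _, slope, slope_var = _slope_fit(y, eta)
    return CalibrationReport(
        expected=expected,
        observed=observed,
        eo_ratio=expected / observed,
        citl=citl,
        citl_variance=citl_var,
        slope=slope,
        slope_variance=slope_var,
    )


def wilson_ci(successes: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion."""
    if n < 1 or not 0 <= successes <= n:
        raise MetricError(f"need 0 <= successes <= n, n >= 1; got {successes}/{n}")
    lower, upper = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    estimate = successes / n
    # guard against float noise at the boundaries: the Wilson interval
    # always contains the point estimate and lies in [0,1]
    lower = min(max(float(lower), 0.0), estimate)
    upper = max(min(float(upper), 1.0), estimate)
    return ProportionCI(estimate=estimate, lower=lower, upper=upper)


def calibration_plot_data(
    probabilities, outcomes, group_count: int = 10
) -> CalibrationPlotData:
    """Equal-size risk groups for a grouped calibration plot.

    Ties in predicted risk are broken by a stable sort on record order, so
    grouped output is deterministic; a warning is raised when a single risk
    value spans group boundaries.
    """
    if group_count < 2:
        raise MetricError("group_count must be >= 2")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < group_count:
        raise MetricError("need at least one record per group")
    order = np.argsort(p, kind="mergesort")  # stable: ties keep record order
    if len(np.unique(p)) < group_count:
        warnings.warn(
            "fewer distinct risk values than groups; groups split ties by record order"
        )
    chunks = np.array_split(order, group_count)
    mean_pred, obs_prop, lo, hi, sizes = [], [], [], [], []
    for idx in chunks:
        k = int(y[idx].sum())
        ci = wilson_ci(k, len(idx))
        mean_pred.append(p[idx].mean())
        obs_prop.append(k / len(idx))
        lo.append(ci.lower)
        hi.append(ci.upper)
        sizes.append(len(idx))
    return CalibrationPlotData(
        mean_predicted=np.array(mean_pred),
        observed_proportion=np.array(obs_prop),
        ci_lower=np.array(lo),
        ci_upper=np.array(hi),
        group_size=np.array(sizes),
        group_count=group_count,
    )
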