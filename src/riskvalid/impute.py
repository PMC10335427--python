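"""Multiple imputation by chained equations (MICE).

Produces m completed copies of a cohort.  Algorithm per imputation:

1. initialise every missing cell with a random draw from the variable's
   observed margin;
2. for each of ``cycles`` iterations, visit the incomplete variables in
   order of increasing missingness and redraw their missing cells from a
   conditional model on *all* other variables including the outcome (and
   judgement flag), which is what makes imputation valid under MAR:

   * binary variables: logistic regression with an approximate posterior
     draw of the coefficients (beta* ~ N(beta_hat, cov)), then Bernoulli
     draws from expit(X beta*);
   * continuous variables: predictive mean matching (type-1) — a Bayesian
     linear regression draw produces predicted means for the missing rows,
     each of which receives the observed value of one of its k=5
     nearest-prediction donors;

3. after the final cycle the completed dataset is emitted; the m runs use
   independent sub-seeds of the spec seed.

Observed cells are never altered; between-imputation variability comes from
the initialisation, the posterior draws and the donor draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import ID, JUDGEMENT, OUTCOME

logger = logging.getLogger(__name__)

LOGISTIC_DRAW = "logistic-draw"
PMM = "predictive-mean-matching"


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class ImputationSpec:
    """m imputations, cycles per imputation, and per-variable methods.

    ``methods`` maps variable name to "logistic-draw" or
    "predictive-mean-matching"; variables not listed default by type
    (binary -> logistic draw, continuous -> PMM with ``pmm_donors``
    donors).
    """

    m: int = 20
    cycles: int = 10
    methods: Mapping[str, str] = field(default_factory=dict)
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ImputationError("m must be >= 2")
        if self.cycles < 1:
            raise ImputationError("cycles must be >= 1")
        for name, method in self.methods.items():
            if method not in (LOGISTIC_DRAW, PMM):
                raise ImputationError(f"unknown method {method!r} for {name!r}")


@dataclass
class ImputedSet:
    datasets: list[pd.DataFrame]
    spec: ImputationSpec

    @property
    def m(self) -> int:
        return len(self.datasets)


def missingness_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variable missingness and the table of distinct missingness patterns.

    Variables missing in every record are flagged with a warning — they
    carry no observed margin to impute from.
    """
    cols = [c for c in table.columns if c != ID]
    n = len(table)
    per_var = pd.DataFrame(
        {
            "variable": cols,
            "n_missing": [int(table[c].isna().sum()) for c in cols],
        }
    )
    per_var["proportion"] = per_var["n_missing"] / n if n else 0.0
    fully_missing = per_var.loc[per_var["n_missing"] == n, "variable"].tolist()
    if fully_missing:
        warnings.warn(f"variable(s) 100% missing: {fully_missing}")
    patterns = (
        table[cols]
        .isna()
        .groupby(cols, as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values("count", ascending=False, ignore_index=True)
    )
    return per_var, patterns


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """Logistic fit returning (params, cov); ridge fallback on separation."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(fit.params, dtype=float)
        cov = np.asarray(fit.cov_params(), dtype=float)
        if np.isfinite(params).all() and np.isfinite(cov).all() and np.abs(params).max() < 30:
            return params, cov
        raise PerfectSeparationError("unstable fit")
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        logger.warning("separation in conditional logistic model; using ridge fallback")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1.0 / max(len(y), 1), L1_wt=0.0
            )
        params = np.asarray(fit.params, dtype=float)
        cov = np.eye(len(params)) * 1e-2  # modest perturbation in lieu of a posterior
        return params, cov


def _impute_logistic(
    data: pd.DataFrame,
    var: str,
    miss: np.ndarray,
    predictors: list[str],
    rng: np.random.Generator,
) -> None:
    obs = ~miss
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in predictors]
    )
    y_obs = data.loc[obs, var].to_numpy(dtype=float)
    if len(np.unique(y_obs)) < 2:
        # degenerate margin: redraw from the observed constant
        data.loc[miss, var] = y_obs[0]
        return
    params, cov = _fit_logistic(X[obs], y_obs)
    # approximate posterior draw of the coefficients
    try:
        draw = rng.multivariate_normal(params, cov, method="cholesky")
    except np.linalg.LinAlgError:
        draw = rng.multivariate_normal(params, cov + 1e-8 * np.eye(len(params)))
    p_miss = expit(X[miss] @ draw)
    data.loc[miss, var] = (rng.random(int(miss.sum())) < p_miss).astype(float)


def _impute_pmm(
    data: pd.DataFrame,
    var: str,
    miss: np.ndarray,
    predictors: list[str],
    rng: np.random.Generator,
    donors: int,
) -> None:
    obs = ~miss
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in predictors]
    )
    X_obs, X_mis = X[obs], X[miss]
    y_obs = data.loc[obs, var].to_numpy(dtype=float)
    n_obs, k = X_obs.shape
    # Bayesian linear regression draw (sigma^2 from scaled inv-chi2, then beta)
    xtx = X_obs.T @ X_obs + 1e-8 * np.eye(k)
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n_obs - k, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    beta_star = rng.multivariate_normal(beta_hat, sigma2 * xtx_inv)
    pred_obs = X_obs @ beta_hat       # donors located with the MLE predictions
    pred_mis = X_mis @ beta_star      # perturbed predictions for the missing rows
    k_donors = min(donors, n_obs)
    order = np.argsort(pred_obs, kind="mergesort")
    sorted_pred = pred_obs[order]
    filled = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, pm)
        lo = max(0, pos - k_donors)
        hi = min(n_obs, pos + k_donors)
        window = order[lo:hi]
        nearest = window[np.argsort(np.abs(pred_obs[window] - pm), kind="mergesort")[:k_donors]]
        filled[i] = y_obs[rng.choice(nearest)]
    data.loc[miss, var] = filled


def _resolve_method(table: pd.DataFrame, var: str, spec: ImputationSpec) -> str:
    if var in spec.methods:
        return spec.methods[var]
    observed = table[var].dropna().unique()
    is_binary = np.isin(observed, (0.0, 1.0)).all()
    return LOGISTIC_DRAW if is_binary else PMM


def mice(table: pd.DataFrame, spec: ImputationSpec) -> ImputedSet:
    """Run chained-equations imputation on a cohort table.

    The outcome (and judgement flag) must be complete; they enter every
    conditional model as predictors but are never imputed.  A table with no
    missing cells short-circuits to m identical copies.
    """
    if ID in table.columns:
        body = table.drop(columns=[ID])
    else:
        body = table
    if OUTCOME in body.columns and body[OUTCOME].isna().any():
        raise ImputationError("outcome must be complete")
    target_vars = [c for c in body.columns if body[c].isna().any()]
    if not target_vars:
        return ImputedSet(datasets=[table.copy() for _ in range(spec.m)], spec=spec)
    for var in target_vars:
        if body[var].notna().sum() == 0:
            raise ImputationError(f"variable {var!r} has no observed values")
    # visit order: increasing missingness
    target_vars.sort(key=lambda c: (int(body[c].isna().sum()), c))
    methods = {v: _resolve_method(body, v, spec) for v in target_vars}
    miss_masks = {v: body[v].isna().to_numpy() for v in target_vars}

    datasets = []
    for i in range(spec.m):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1000 + i]))
        data = body.copy().astype(float)
        for var in target_vars:
            observed = data[var].dropna().to_numpy()
            data.loc[miss_masks[var], var] = rng.choice(observed, size=miss_masks[var].sum())
        for _ in range(spec.cycles):
            for var in target_vars:
                predictors = [c for c in data.columns if c != var]
                if methods[var] == LOGISTIC_DRAW:
                    _impute_logistic(data, var, miss_masks[var], predictors, rng)
                else:
                    _impute_pmm(data, var, miss_masks[var], predictors, rng, spec.pmm_donors)
        completed = data
        for var, method in methods.items():
            if method == LOGISTIC_DRAW:
                completed[var] = completed[var].astype(float)
        if ID in table.columns:
            completed.insert(0, ID, table[ID].to_numpy())
        datasets.append(completed)
    return ImputedSet(datasets=datasets, spec=spec)
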