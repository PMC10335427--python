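"""End-to-end external validation workflow.

Stages, in order: (optional) cohort synthesis -> missingness summary and
effective-sample-size check -> chained-equations imputation -> per-imputation
scoring and performance -> Rubin pooling -> recalibration (intercept-only vs
slope-and-intercept, with selection) -> post-update performance -> threshold
sweep -> clinical-judgement comparator -> decision curve analysis -> report
serialisation.  Every stage draws its randomness from a named sub-seed of
the master seed, so a full run is deterministic and stages can be rerun in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import (
    counts_from_flags,
    default_threshold_grid,
    metrics_from_counts,
    threshold_sweep,
)
from .netbenefit import dca_curve, default_dca_grid, pool_dca_curves
from .cohort import (
    ID,
    OUTCOME,
    Cohort,
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    read_cohort,
)
from .impute import ImputationSpec, mice, missingness_summary
from .metrics import calibration, calibration_plot_data, discrimination
from .model import RiskModel, default_model, load_model, save_model
from .pooling import PooledEstimate, pool_report, rubin_pool
from .recalibrate import (
    INTERCEPT_ONLY,
    update_intercept,
    update_slope_intercept,
)


@dataclass
class RunConfig:
    """Everything a full validation run needs.

    Either ``cohort_path`` (CSV produced by :func:`riskvalid.cohort.write_cohort`)
    or a ``cohort_spec`` for synthesis; a model path or None for the shipped
    default; imputation settings; threshold and DCA grids; the master seed;
    and the Brier tolerance used to choose between recalibration forms.
    """

    model_path: str | None = None
    cohort_path: str | None = None
    cohort_spec: CohortSpec | None = None
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    threshold_grid: Sequence[float] | None = None
    dca_grid: Sequence[float] | None = None
    selection_tolerance: float = 0.005
    calibration_groups: int = 10
    seed: int = 0
    output_dir: str | None = None

    def resolve_model(self) -> RiskModel:
        return load_model(self.model_path) if self.model_path else default_model()

    def resolve_cohort(self) -> Cohort:
        if self.cohort_path:
            return read_cohort(self.cohort_path)
        spec = self.cohort_spec or default_cohort_spec(seed=self.seed)
        if spec.seed != self.seed:
            spec = dataclasses.replace(spec, seed=self.seed)
        return generate_cohort(spec)


def check_sample_size(outcomes, minimum: int = 100) -> dict:
    """External-validation effective-sample-size rule: at least ``minimum``
    participants with and without the event."""
    y = np.asarray(outcomes, dtype=int)
    events = int(y.sum())
    non_events = int(len(y) - events)
    return {
        "events": events,
        "non_events": non_events,
        "minimum": minimum,
        "pass": bool(events >= minimum and non_events >= minimum),
    }


def summarise_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-predictor distribution overall and by outcome, with group tests.

    Binary predictors: n (%) observed positive plus the missing count, and a
    chi-square test of association with the outcome (Fisher's exact test
    when any expected cell is below 5).  Age: mean (SD) and a two-sample
    t-test.  Empty strata yield an undefined (NaN) p-value.
    """
    table = cohort.table
    y = table[OUTCOME].to_numpy(dtype=int)
    rows = []
    n = len(table)
    rows.append(
        {
            "variable": OUTCOME, "summary": "n (%)",
            "overall": f"{int(y.sum())} ({100 * y.mean():.0f})",
            "events": "-", "non_events": "-", "n_missing": 0, "p_value": np.nan,
        }
    )
    for name in cohort.predictor_columns:
        col = table[name]
        miss = int(col.isna().sum())
        if name == "age":
            obs = col.dropna()
            by = [col[y == 1].dropna(), col[y == 0].dropna()]
            if len(by[0]) > 1 and len(by[1]) > 1:
                p = float(sps.ttest_ind(by[0], by[1], equal_var=False).pvalue)
            else:
                p = np.nan
            rows.append(
                {
                    "variable": name, "summary": "mean (SD)",
                    "overall": f"{obs.mean():.1f} ({obs.std():.1f})",
                    "events": f"{by[0].mean():.1f} ({by[0].std():.1f})" if len(by[0]) else "-",
                    "non_events": f"{by[1].mean():.1f} ({by[1].std():.1f})" if len(by[1]) else "-",
                    "n_missing": miss, "p_value": p,
                }
            )
            continue
        obs_mask = col.notna()
        x = col[obs_mask].to_numpy(dtype=float)
        y_obs = y[obs_mask.to_numpy()]
        crosstab = np.array(
            [
                [np.sum((x == 1) & (y_obs == 1)), np.sum((x == 1) & (y_obs == 0))],
                [np.sum((x == 0) & (y_obs == 1)), np.sum((x == 0) & (y_obs == 0))],
            ]
        )
        if crosstab.sum(axis=0).min() == 0 or crosstab.sum(axis=1).min() == 0:
            p = np.nan
        else:
            expected = np.outer(crosstab.sum(axis=1), crosstab.sum(axis=0)) / crosstab.sum()
            if expected.min() < 5:
                p = float(sps.fisher_exact(crosstab)[1])
            else:
                p = float(sps.chi2_contingency(crosstab, correction=False)[1])

        def cell(mask) -> str:
            sub = col[mask & obs_mask]
            denom = int((mask & obs_mask).sum())
            k = int(sub.sum())
            return f"{k} ({100 * k / denom:.0f})" if denom else "-"

        pos = pd.Series(y == 1, index=table.index)
        rows.append(
            {
                "variable": name, "summary": "n (%)",
                "overall": cell(pd.Series(True, index=table.index)),
                "events": cell(pos), "non_events": cell(~pos),
                "n_missing": miss, "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _performance_dict(probabilities, eta, outcomes) -> dict:
    d = discrimination(probabilities, outcomes)
    c = calibration(eta, outcomes)
    return {
        "auc": d.auc,
        "auc_variance": d.auc_variance,
        "brier": d.brier,
        "expected": c.expected,
        "observed": c.observed,
        "eo_ratio": c.eo_ratio,
        "citl": c.citl,
        "citl_variance": c.citl_variance,
        "slope": c.slope,
        "slope_variance": c.slope_variance,
    }


def _pooled_to_jsonable(pooled: Mapping) -> dict:
    out = {}
    for key, val in pooled.items():
        if isinstance(val, PooledEstimate):
            out[key] = {
                "estimate": val.qbar,
                "ci_lower": val.ci[0],
                "ci_upper": val.ci[1],
                "within": val.within,
                "between": val.between,
                "total": val.total,
                "m": val.m,
            }
        else:
            out[key] = val
    return out


@dataclass
class StudyReport:
    """All stage outputs of one validation run."""

    config_seed: int
    cohort_summary: pd.DataFrame
    missingness: pd.DataFrame
    missingness_patterns: pd.DataFrame
    sample_size: dict
    per_imputation: list[dict]
    pooled_before: dict
    per_imputation_after: list[dict]
    pooled_after: dict
    recalibration: dict
    updated_model: RiskModel
    threshold_sweep: pd.DataFrame
    judgement: dict
    dca: pd.DataFrame
    calibration_plot: dict

    def to_jsonable(self) -> dict:
        return {
            "seed": self.config_seed,
            "sample_size": self.sample_size,
            "missingness": self.missingness.to_dict(orient="records"),
            "pooled_before_update": self.pooled_before,
            "pooled_after_update": self.pooled_after,
            "recalibration": self.recalibration,
            "per_imputation_before": self.per_imputation,
            "per_imputation_after": self.per_imputation_after,
            "judgement": self.judgement,
            "threshold_sweep": self.threshold_sweep.to_dict(orient="records"),
            "dca": self.dca.to_dict(orient="records"),
            "calibration_plot": self.calibration_plot,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            _round_floats(self.to_jsonable()), indent=indent, sort_keys=True
        )


def _round_floats(obj, digits: int = 4):
    """Round every float in a nested structure; makes reports hash-stable."""
    if isinstance(obj, float):
        return 0.0 if obj == 0 else round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _judgement_report(flags, outcomes) -> dict:
    counts = counts_from_flags(flags, outcomes)
    m = metrics_from_counts(counts)
    out = {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn}
    for label, ci in (
        ("sensitivity", m.sensitivity), ("specificity", m.specificity),
        ("ppv", m.ppv), ("npv", m.npv),
    ):
        out[label] = ci.estimate if ci else None
        out[f"{label}_ci"] = [ci.lower, ci.upper] if ci else None
    return out


def run_validation(config: RunConfig) -> StudyReport:
    """Execute the full validation workflow; deterministic given the seed."""
    model = config.resolve_model()
    cohort = config.resolve_cohort()
    table = cohort.table

    per_var, patterns = missingness_summary(table)
    size_check = check_sample_size(cohort.outcomes)
    summary = summarise_cohort(cohort)

    imput_spec = config.imputation
    if imput_spec.seed != config.seed:
        imput_spec = dataclasses.replace(imput_spec, seed=config.seed)
    imputed = mice(table, imput_spec)

    y = cohort.outcomes
    df_com = max(len(y) - (len(model.predictors) + 1), 1)

    per_imp = []
    etas = []
    for data in imputed.datasets:
        eta = model.linear_predictor(data)
        etas.append(eta)
        from scipy.special import expit

        per_imp.append(_performance_dict(expit(eta), eta, y))
    pooled_before = pool_report(per_imp, df_com=df_com)

    # recalibration per imputed dataset, parameters pooled by Rubin's rules,
    # then one final updated model built from the pooled parameters
    int_results = [update_intercept(model, eta, y) for eta in etas]
    slope_results = [update_slope_intercept(model, eta, y) for eta in etas]
    delta_pool = rubin_pool(
        [r.delta for r in int_results],
        [r.delta_variance for r in int_results],
        df_com=df_com,
    )
    gamma_pool = rubin_pool(
        [r.gamma for r in slope_results],
        [r.gamma_variance for r in slope_results],
        df_com=df_com,
    )
    brier_int = float(np.mean([r.brier_after for r in int_results]))
    brier_slope = float(np.mean([r.brier_after for r in slope_results]))
    chosen_method = (
        "slope_and_intercept"
        if brier_slope < brier_int - config.selection_tolerance
        else INTERCEPT_ONLY
    )
    from .model import rescale, shift_intercept

    if chosen_method == INTERCEPT_ONLY:
        updated_model = shift_intercept(model, delta_pool.qbar)
        etas_after = [eta + delta_pool.qbar for eta in etas]
    else:
        delta_s = float(np.mean([r.delta for r in slope_results]))
        updated_model = rescale(
            model, gamma_pool.qbar, model.constant * gamma_pool.qbar + delta_s
        )
        etas_after = [delta_s + gamma_pool.qbar * eta for eta in etas]

    from scipy.special import expit

    per_imp_after = [
        _performance_dict(expit(eta), eta, y) for eta in etas_after
    ]
    pooled_after = pool_report(per_imp_after, df_com=df_com)

    recal_report = {
        "method": chosen_method,
        "delta": {
            "estimate": delta_pool.qbar,
            "ci_lower": delta_pool.ci[0],
            "ci_upper": delta_pool.ci[1],
        },
        "gamma": {
            "estimate": gamma_pool.qbar,
            "ci_lower": gamma_pool.ci[0],
            "ci_upper": gamma_pool.ci[1],
        },
        "brier_intercept_only": brier_int,
        "brier_slope_and_intercept": brier_slope,
        "selection_tolerance": config.selection_tolerance,
    }

    # threshold sweep: metrics pooled across imputations at each cut-off
    grid = (
        np.asarray(config.threshold_grid, dtype=float)
        if config.threshold_grid is not None
        else default_threshold_grid()
    )
    sweeps = [
        threshold_sweep(expit(eta), y, grid) for eta in etas_after
    ]
    sweep = pd.concat(sweeps).groupby("threshold", as_index=False).mean()
    for col in ("tp", "fp", "fn", "tn", "n_flagged"):
        sweep[col] = sweep[col].round().astype(int)

    judgement = _judgement_report(cohort.judgement, y)

    dca_grid = (
        np.asarray(config.dca_grid, dtype=float)
        if config.dca_grid is not None
        else default_dca_grid()
    )
    curves = [
        dca_curve(expit(eta), y, cohort.judgement, dca_grid) for eta in etas_after
    ]
    dca = pool_dca_curves(curves)

    # calibration plot from the first imputed dataset (single-dataset view)
    plot = calibration_plot_data(
        expit(etas_after[0]), y, group_count=config.calibration_groups
    )
    plot_dict = {
        "mean_predicted": plot.mean_predicted.tolist(),
        "observed_proportion": plot.observed_proportion.tolist(),
        "ci_lower": plot.ci_lower.tolist(),
        "ci_upper": plot.ci_upper.tolist(),
        "group_size": plot.group_size.tolist(),
    }

    return StudyReport(
        config_seed=config.seed,
        cohort_summary=summary,
        missingness=per_var,
        missingness_patterns=patterns,
        sample_size=size_check,
        per_imputation=per_imp,
        pooled_before=_pooled_to_jsonable(pooled_before),
        per_imputation_after=per_imp_after,
        pooled_after=_pooled_to_jsonable(pooled_after),
        recalibration=recal_report,
        updated_model=updated_model,
        threshold_sweep=sweep,
        judgement=judgement,
        dca=dca,
        calibration_plot=plot_dict,
    )


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Serialise a StudyReport: JSON master report plus per-table CSVs and
    the updated model in the loadable schema."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    report.cohort_summary.to_csv(out / "cohort_summary.csv", index=False, float_format="%.4f")
    report.missingness.to_csv(out / "missingness.csv", index=False, float_format="%.4f")
    report.threshold_sweep.to_csv(out / "threshold_sweep.csv", index=False, float_format="%.4f")
    report.dca.to_csv(out / "dca_curve.csv", index=False, float_format="%.4f")
    save_model(report.updated_model, out / "updated_model.yaml")
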