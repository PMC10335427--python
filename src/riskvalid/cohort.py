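"""Seeded synthetic cohort generator.

The validation study this package targets drew on ~1145 individuals assessed
by early-intervention-in-psychosis services, with 15 binary predictors plus
age, an 11% 12-month violence outcome, per-variable missingness up to 46%,
and a binary clinician-judgement flag (~40% sensitivity, ~89% specificity
against the outcome).  Real EHR data of this kind cannot be shared, so this
module generates cohorts with the same statistical shape:

* binary predictors from a latent Gaussian copula thresholded at
  ``Phi^-1(1 - prevalence)``, so marginal prevalences hit their targets while
  a configurable latent correlation (default: 0.2 within the
  antisocial-history block) supplies realistic dependence;
* age from a truncated normal (mean 25, SD 10, range 14-65);
* outcomes drawn from a known logistic "truth" model whose intercept is
  solved numerically so the realised prevalence matches the target;
* a judgement flag generated from the outcome alone at the stated
  sensitivity/specificity;
* missing-at-random masking driven by a logistic model on fully observed
  columns (sex, age, outcome), with the intercept solved per variable to hit
  the target missingness rate.

Everything is deterministic given the spec's seed: the master seed spawns a
named sub-seed per stage, so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .model import RiskModel, default_model

OUTCOME = "outcome"
JUDGEMENT = "judgement"
ID = "id"

# Predictors sharing a latent antisocial/adversity factor in the default spec.
ANTISOCIAL_BLOCK = (
    "previous_violent_crime",
    "previous_drug_misuse",
    "previous_alcohol_misuse",
    "parent_drug_alcohol_misuse",
    "parent_violent_crime",
    "sibling_violent_crime",
    "dependence_treatment",
)

# Stage labels -> offsets used to spawn named sub-seeds from a master seed.
_STAGES = {"predictors": 0, "outcome": 1, "judgement": 2, "missingness": 3}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


class CohortSpecError(ValueError):
    pass


@dataclass(frozen=True)
class AgeSpec:
    """Target realised moments of age within the service age band.

    ``mean``/``sd`` are the moments the generated cohort should show (the
    reference cohort reports mean 25, SD 10); the truncated-normal parent
    parameters are solved from them, since naive truncation of N(25, 10²)
    to [14, 65] would inflate the realised mean to ~27.5.  The solved
    parent is a far-tail normal whose density decreases over the band —
    a right-skewed age profile typical of early-intervention services.
    """

    mean: float = 25.0
    sd: float = 10.0
    minimum: float = 14.0
    maximum: float = 65.0

    def parent_params(self) -> tuple[float, float]:
        """(loc, scale) of the parent normal whose truncation to
        [minimum, maximum] has the target mean and sd."""
        from scipy.optimize import fsolve

        lo, hi = self.minimum, self.maximum

        def resid(params):
            loc, scale = params
            scale = abs(scale)
            a, b = (lo - loc) / scale, (hi - loc) / scale
            m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
            return [m - self.mean, np.sqrt(v) - self.sd]

        sol, info, ier, _ = fsolve(
            resid, [self.mean - self.sd, 1.5 * self.sd], full_output=True
        )
        if ier != 1 or max(abs(np.asarray(resid(sol)))) > 1e-6:
            # no admissible parent (e.g. sd too large for the band): fall back
            # to the literal parameters
            return self.mean, self.sd
        return float(sol[0]), float(abs(sol[1]))


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one cohort, including the truth model."""

    n: int
    predictor_marginals: Mapping[str, float]
    age: AgeSpec
    outcome_model: RiskModel
    target_prevalence: float = 0.11
    judgement_sensitivity: float = 0.40
    judgement_specificity: float = 0.89
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    latent_correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortSpecError("n must be >= 1")
        for name, p in self.predictor_marginals.items():
            if not 0.0 <= p <= 1.0:
                raise CohortSpecError(f"marginal for {name!r} outside [0,1]: {p}")
        if not 0.0 < self.target_prevalence < 1.0:
            raise CohortSpecError("target_prevalence must be in (0,1)")
        for label, v in (
            ("judgement_sensitivity", self.judgement_sensitivity),
            ("judgement_specificity", self.judgement_specificity),
        ):
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"{label} outside [0,1]: {v}")
        for name, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise CohortSpecError(f"missing rate for {name!r} outside [0,1]: {r}")
            if name in (OUTCOME, JUDGEMENT):
                raise CohortSpecError(f"{name} may not be masked")

    @property
    def binary_names(self) -> tuple[str, ...]:
        return tuple(self.predictor_marginals)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["age"] = dataclasses.asdict(self.age)
        d["predictor_marginals"] = dict(self.predictor_marginals)
        d["missing_rates"] = dict(self.missing_rates)
        d["outcome_model"] = {
            "label": self.outcome_model.label,
            "constant": self.outcome_model.constant,
            "predictors": [dataclasses.asdict(p) for p in self.outcome_model.predictors],
        }
        if self.latent_correlation is not None:
            d["latent_correlation"] = np.asarray(self.latent_correlation).tolist()
        return d


# Table-1-style defaults: marginal prevalences of the 15 binary items and the
# per-variable missingness rates of the reference validation cohort.  The
# three-level education item is collapsed to the binary "lower secondary"
# indicator the default model uses.
DEFAULT_MARGINALS: dict[str, float] = {
    "male": 0.60,
    "previous_violent_crime": 0.09,
    "previous_drug_misuse": 0.21,
    "previous_alcohol_misuse": 0.07,
    "previous_self_harm": 0.43,
    "lower_secondary_education": 0.30,
    "parent_drug_alcohol_misuse": 0.12,
    "parent_violent_crime": 0.03,
    "sibling_violent_crime": 0.02,
    "current_inpatient": 0.19,
    "antipsychotic_treatment": 0.50,
    "antidepressant_treatment": 0.33,
    "dependence_treatment": 0.01,
    "low_income": 0.17,
    "benefit_recipient": 0.14,
}

DEFAULT_MISSING_RATES: dict[str, float] = {
    "previous_violent_crime": 0.01,
    "previous_drug_misuse": 0.003,
    "previous_alcohol_misuse": 0.002,
    "previous_self_harm": 0.003,
    "lower_secondary_education": 0.14,
    "parent_drug_alcohol_misuse": 0.12,
    "parent_violent_crime": 0.43,
    "sibling_violent_crime": 0.46,
    "dependence_treatment": 0.001,
    "low_income": 0.01,
    "benefit_recipient": 0.05,
}


def default_block_correlation(
    names: tuple[str, ...], block: tuple[str, ...] = ANTISOCIAL_BLOCK, rho: float = 0.2
) -> np.ndarray:
    """Unit-diagonal matrix with constant ``rho`` within ``block``, 0 elsewhere.

    Constant positive correlation within a block is positive semi-definite
    for any 0 <= rho <= 1 (one-factor structure).
    """
    k = len(names)
    corr = np.eye(k)
    idx = [i for i, n in enumerate(names) if n in block]
    for a in idx:
        for b in idx:
            if a != b:
                corr[a, b] = rho
    return corr


def default_cohort_spec(
    n: int = 1145, seed: int = 0, model: RiskModel | None = None
) -> CohortSpec:
    model = model if model is not None else default_model()
    # latent order: binary names then age
    names = tuple(DEFAULT_MARGINALS) + ("age",)
    return CohortSpec(
        n=n,
        predictor_marginals=dict(DEFAULT_MARGINALS),
        age=AgeSpec(),
        outcome_model=model,
        target_prevalence=0.11,
        judgement_sensitivity=0.40,
        judgement_specificity=0.89,
        missing_rates=dict(DEFAULT_MISSING_RATES),
        latent_correlation=default_block_correlation(names),
        seed=seed,
    )


def _check_correlation(corr: np.ndarray, k: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise CohortSpecError(
            f"latent correlation must be {k}x{k}, got {corr.shape}"
        )
    if not np.allclose(corr, corr.T):
        raise CohortSpecError("latent correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise CohortSpecError("latent correlation matrix must have unit diagonal")
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-8:
        raise CohortSpecError(
            f"latent correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g})"
        )
    return corr


def generate_predictors(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a complete predictor table (binary items + age) for ``spec.n``.

    Binary item j is 1 iff its latent Gaussian exceeds ``Phi^-1(1 - p_j)``;
    age maps its latent coordinate through the truncated-normal quantile
    function, so the copula carries any declared age correlation too.
    """
    rng = rng if rng is not None else stage_rng(spec.seed, "predictors")
    names = spec.binary_names
    k = len(names) + 1  # + age
    if spec.latent_correlation is None:
        corr = np.eye(k)
    else:
        corr = _check_correlation(spec.latent_correlation, k)
    # jitter for numerical PSD before Cholesky
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
    z = rng.standard_normal((spec.n, k)) @ chol.T

    table = pd.DataFrame(index=pd.RangeIndex(spec.n))
    for j, name in enumerate(names):
        p = spec.predictor_marginals[name]
        thr = norm.ppf(1.0 - p)  # P(z > thr) = p; p=0 -> +inf -> all zeros
        table[name] = (z[:, j] > thr).astype(int)
    loc, scale = spec.age.parent_params()
    a = (spec.age.minimum - loc) / scale
    b = (spec.age.maximum - loc) / scale
    u = norm.cdf(z[:, -1])
    # keep the quantile strictly inside (0,1)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    table["age"] = truncnorm.ppf(u, a, b, loc=loc, scale=scale)
    return table


def solve_intercept(model: RiskModel, predictors: pd.DataFrame, target: float) -> float:
    """Constant alpha* making the mean predicted risk over ``predictors`` equal ``target``.

    The mean of ``expit(alpha + s_i)`` is strictly increasing in alpha, so a
    bracketed root always exists for 0 < target < 1; solved to 1e-10.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must be in (0,1)")
    base = model.linear_predictor(predictors) - model.constant  # s_i = sum beta x

    def f(alpha: float) -> float:
        return float(expit(alpha + base).mean() - target)

    lo, hi = -50.0, 50.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"no intercept root in [{lo}, {hi}]: f(lo)={flo:.3g}, f(hi)={fhi:.3g}"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def generate_outcomes(
    model: RiskModel, predictors: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli outcomes from the truth model: y_i ~ Bern(expit(eta_i))."""
    p = model.predict_proba(predictors)
    return (rng.random(len(predictors)) < p).astype(int)


def generate_judgement(
    y: np.ndarray, sensitivity: float, specificity: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary clinician flag: P(flag|y=1)=sens, P(flag|y=0)=1-spec."""
    y = np.asarray(y)
    u = rng.random(y.shape[0])
    p_flag = np.where(y == 1, sensitivity, 1.0 - specificity)
    return (u < p_flag).astype(int)


# MAR driver slopes: masking depends on sex, standardised age and outcome,
# all fully observed, so the mechanism is missing-at-random by construction.
_MAR_SLOPES = {"male": 0.3, "age_std": -0.2, OUTCOME: 0.4}


def apply_missingness(
    table: pd.DataFrame,
    missing_rates: Mapping[str, float],
    rng: np.random.Generator,
    age_mean: float = 25.0,
    age_sd: float = 10.0,
) -> pd.DataFrame:
    """Mask predictor cells MAR; the outcome and judgement are never masked.

    Per variable the masking probability is logistic in (male, age, outcome)
    with fixed slopes; the intercept is solved so the expected masked
    fraction equals the target rate.
    """
    for name in missing_rates:
        if name in (OUTCOME, JUDGEMENT):
            raise CohortSpecError(f"{name} may not be masked")
        if name not in table.columns:
            raise CohortSpecError(f"missing rate given for absent column {name!r}")
    out = table.copy()
    driver = (
        _MAR_SLOPES["male"] * table["male"].to_numpy(dtype=float)
        + _MAR_SLOPES["age_std"] * (table["age"].to_numpy(dtype=float) - age_mean) / age_sd
        + _MAR_SLOPES[OUTCOME] * table[OUTCOME].to_numpy(dtype=float)
    )
    for name, rate in missing_rates.items():
        if rate <= 0.0:
            continue
        if rate >= 1.0:
            out[name] = np.nan
            continue

        def f(a: float) -> float:
            return float(expit(a + driver).mean() - rate)

        alpha = brentq(f, -50.0, 50.0, xtol=1e-10)
        mask = rng.random(len(table)) < expit(alpha + driver)
        col = out[name].astype(float)
        col[mask] = np.nan
        out[name] = col
    return out


@dataclass
class Cohort:
    """A generated (or loaded) cohort table plus its provenance."""

    table: pd.DataFrame
    spec: CohortSpec | None = None
    true_model: RiskModel | None = None  # truth model with solved intercept

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def outcomes(self) -> np.ndarray:
        return self.table[OUTCOME].to_numpy(dtype=int)

    @property
    def judgement(self) -> np.ndarray:
        return self.table[JUDGEMENT].to_numpy(dtype=int)

    @property
    def predictor_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in (ID, OUTCOME, JUDGEMENT)]


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full generation: predictors -> solved intercept -> outcomes ->
    judgement -> MAR masking.  Deterministic given ``spec.seed``."""
    predictors = generate_predictors(spec)
    alpha = solve_intercept(spec.outcome_model, predictors, spec.target_prevalence)
    truth = dataclasses.replace(spec.outcome_model, constant=alpha)
    y = generate_outcomes(truth, predictors, stage_rng(spec.seed, "outcome"))
    flag = generate_judgement(
        y, spec.judgement_sensitivity, spec.judgement_specificity,
        stage_rng(spec.seed, "judgement"),
    )
    full = predictors.copy()
    full[OUTCOME] = y
    full[JUDGEMENT] = flag
    masked = apply_missingness(
        full, spec.missing_rates, stage_rng(spec.seed, "missingness"),
        age_mean=spec.age.mean, age_sd=spec.age.sd,
    )
    masked.insert(0, ID, np.arange(spec.n))
    return Cohort(table=masked, spec=spec, true_model=truth)


def write_cohort(cohort: Cohort, csv_path: str | Path) -> None:
    """CSV with empty fields for missing values + sidecar provenance JSON."""
    csv_path = Path(csv_path)
    cohort.table.to_csv(csv_path, index=False, float_format="%.6f", na_rep="")
    if cohort.spec is not None:
        sidecar = csv_path.with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(cohort.spec.to_jsonable(), indent=2, sort_keys=True))


def read_cohort(csv_path: str | Path) -> Cohort:
    table = pd.read_csv(csv_path)
    return Cohort(table=table)
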