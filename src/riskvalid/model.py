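"""Logistic risk-model representation and scoring.

A risk model of the OxMIV family is a plain logistic model: a set of named
predictors (binary items plus continuous age), each carrying a log-odds
coefficient, combined with a constant.  The linear predictor is

    eta = constant + sum_j beta_j * (x_j - center_j)

and the predicted 12-month risk is ``expit(eta)``.  When one or more items
are unknown at assessment time the model reports a lower and upper band of
possible risks instead of a point estimate, obtained by giving each unknown
item its minimum / maximum achievable contribution (binary: {0, beta};
continuous: the declared range of the variable).

Models are configuration-driven: coefficients live in a YAML/JSON file, not
in code, so published weights can be dropped in without touching the
package.  The shipped default (``data/oxmiv_like.yaml``) is a synthetic
16-predictor model whose coefficient signs follow the risk directions seen
in first-episode-psychosis cohorts; it is not the published OxMIV weight
set, which is not reproduced here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit


class ModelError(ValueError):
    """Base class for model definition / evaluation errors."""


class ModelParseError(ModelError):
    """Raised when a model file is malformed; message names the offending key."""


class ModelValidationError(ModelError):
    """Raised when a parsed model violates an invariant."""


class MissingPredictorError(KeyError, ModelError):
    """Raised when a record does not cover every model predictor."""


#: Sentinel accepted (alongside None and NaN) to mark an item as not assessed.
UNKNOWN = "unknown"

BINARY = "binary"
CONTINUOUS = "continuous"


def _is_unknown(value) -> bool:
    if value is None or (isinstance(value, str) and value == UNKNOWN):
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class PredictorDef:
    """One model item: a name, its type and its log-odds weight.

    ``center`` is subtracted from continuous values before weighting (the
    default config centres age at 25 years, the cohort mean, so the constant
    is interpretable at the average age).  ``minimum``/``maximum`` declare
    the plausible range of a continuous item; they are required to compute
    risk bands when the item is unknown.
    """

    name: str
    kind: str
    coefficient: float
    center: float = 0.0
    minimum: float | None = None
    maximum: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (BINARY, CONTINUOUS):
            raise ModelValidationError(
                f"predictor {self.name!r}: kind must be 'binary' or 'continuous', "
                f"got {self.kind!r}"
            )
        if not math.isfinite(self.coefficient):
            raise ModelValidationError(
                f"predictor {self.name!r}: coefficient must be finite"
            )

    def contribution(self, value: float) -> float:
        if self.kind == BINARY:
            if value not in (0, 1):
                raise ModelValidationError(
                    f"predictor {self.name!r}: binary value must be 0 or 1, got {value!r}"
                )
            return self.coefficient * value
        value = float(value)
        if not math.isfinite(value):
            raise ModelValidationError(
                f"predictor {self.name!r}: continuous value must be finite"
            )
        return self.coefficient * (value - self.center)

    def contribution_range(self) -> tuple[float, float]:
        """Min/max achievable contribution when the item is unknown."""
        if self.kind == BINARY:
            return min(0.0, self.coefficient), max(0.0, self.coefficient)
        if self.minimum is None or self.maximum is None:
            raise ModelValidationError(
                f"predictor {self.name!r}: unknown continuous item needs a declared "
                "minimum/maximum range"
            )
        ends = (
            self.coefficient * (self.minimum - self.center),
            self.coefficient * (self.maximum - self.center),
        )
        return min(ends), max(ends)


@dataclass(frozen=True)
class RiskModel:
    """An ordered set of :class:`PredictorDef` plus an intercept."""

    predictors: tuple[PredictorDef, ...]
    constant: float
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.predictors) < 1:
            raise ModelValidationError("a model needs at least one predictor")
        names = [p.name for p in self.predictors]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ModelValidationError(
                f"duplicate predictor name(s): {sorted(dupes)}"
            )
        if not math.isfinite(self.constant):
            raise ModelValidationError("constant must be finite")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.predictors)

    def __getitem__(self, name: str) -> PredictorDef:
        for p in self.predictors:
            if p.name == name:
                return p
        raise MissingPredictorError(name)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Vectorised eta over a complete cohort table (no unknowns allowed)."""
        missing = [p.name for p in self.predictors if p.name not in table.columns]
        if missing:
            raise MissingPredictorError(
                f"table lacks model predictor column(s): {missing}"
            )
        eta = np.full(len(table), self.constant, dtype=float)
        for p in self.predictors:
            col = table[p.name].to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ModelValidationError(
                    f"predictor {p.name!r} has missing values; impute before scoring"
                )
            if p.kind == BINARY:
                eta += p.coefficient * col
            else:
                eta += p.coefficient * (col - p.center)
        return eta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table))


@dataclass(frozen=True)
class RiskPrediction:
    """Point risk for one individual, with bands when items were unknown."""

    linear_predictor: float
    probability: float
    bounds: tuple[float, float] | None = None

    @property
    def has_bounds(self) -> bool:
        return self.bounds is not None


def load_model(path: str | Path) -> RiskModel:
    """Read a model definition from a YAML (or JSON) file.

    Schema::

        label: <text>
        constant: <float>
        predictors:
          - {name: ..., kind: binary|continuous, coefficient: ...,
             center: ..., minimum: ..., maximum: ...}
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ModelParseError(f"cannot parse model file {path}: {exc}") from exc
    return model_from_dict(raw, source=str(path))


def model_from_dict(raw: Mapping, source: str = "<dict>") -> RiskModel:
    if not isinstance(raw, Mapping):
        raise ModelParseError(f"{source}: top level must be a mapping")
    for key in ("constant", "predictors"):
        if key not in raw:
            raise ModelParseError(f"{source}: missing required key {key!r}")
    preds = []
    for i, entry in enumerate(raw["predictors"]):
        for key in ("name", "kind", "coefficient"):
            if key not in entry:
                raise ModelParseError(
                    f"{source}: predictor #{i} missing required key {key!r}"
                )
        try:
            coefficient = float(entry["coefficient"])
        except (TypeError, ValueError):
            raise ModelParseError(
                f"{source}: predictor {entry['name']!r} key 'coefficient' is not a number"
            ) from None
        preds.append(
            PredictorDef(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                coefficient=coefficient,
                center=float(entry.get("center", 0.0)),
                minimum=(None if entry.get("minimum") is None else float(entry["minimum"])),
                maximum=(None if entry.get("maximum") is None else float(entry["maximum"])),
            )
        )
    return RiskModel(
        predictors=tuple(preds),
        constant=float(raw["constant"]),
        label=str(raw.get("label", "")),
    )


def default_model() -> RiskModel:
    """The shipped synthetic 16-item model (15 binary items + age)."""
    text = resources.files("riskvalid.data").joinpath("oxmiv_like.yaml").read_text()
    return model_from_dict(yaml.safe_load(text), source="oxmiv_like.yaml")


def save_model(model: RiskModel, path: str | Path) -> None:
    """Write a model in the same schema ``load_model`` reads."""
    doc = {
        "label": model.label,
        "constant": float(model.constant),
        "predictors": [
            {
                "name": p.name,
                "kind": p.kind,
                "coefficient": float(p.coefficient),
                **({"center": p.center} if p.center else {}),
                **({"minimum": p.minimum} if p.minimum is not None else {}),
                **({"maximum": p.maximum} if p.maximum is not None else {}),
            }
            for p in model.predictors
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def predict(model: RiskModel, record: Mapping[str, object]) -> RiskPrediction:
    """Score one individual; returns risk bands if any item is unknown.

    ``record`` must supply a value (or an unknown marker: None, NaN or the
    string ``"unknown"``) for every model predictor.
    """
    eta = model.constant
    lo_extra = 0.0
    hi_extra = 0.0
    any_unknown = False
    for p in model.predictors:
        if p.name not in record:
            raise MissingPredictorError(p.name)
        value = record[p.name]
        if _is_unknown(value):
            any_unknown = True
            lo, hi = p.contribution_range()
            lo_extra += lo
            hi_extra += hi
        else:
            eta += p.contribution(value)
    probability = float(expit(eta))
    bounds = None
    if any_unknown:
        bounds = (float(expit(eta + lo_extra)), float(expit(eta + hi_extra)))
    return RiskPrediction(linear_predictor=float(eta), probability=probability, bounds=bounds)


def shift_intercept(model: RiskModel, delta: float) -> RiskModel:
    """Return a copy with the constant moved by ``delta`` (log-odds)."""
    if not math.isfinite(delta):
        raise ModelValidationError("delta must be finite")
    return replace(model, constant=model.constant + delta)


def rescale(model: RiskModel, slope: float, new_constant: float) -> RiskModel:
    """Multiply every coefficient by ``slope`` and replace the constant.

    This is the slope-and-intercept recalibration transform: with
    ``new_constant = delta + slope * constant`` the rescaled model's linear
    predictor is exactly ``delta + slope * eta``.
    """
    if not math.isfinite(slope) or slope == 0.0:
        raise ModelValidationError("slope must be finite and nonzero")
    preds = tuple(replace(p, coefficient=p.coefficient * slope) for p in model.predictors)
    return replace(model, predictors=preds, constant=float(new_constant))
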