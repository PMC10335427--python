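"""Rubin's rules for combining estimates across multiply imputed datasets.

With per-imputation estimates Q_1..Q_m and variances U_1..U_m:

    Qbar = mean(Q),  W = mean(U),  B = var(Q, ddof=1),
    T = W + (1 + 1/m) B

and the CI uses a t reference with Rubin's degrees of freedom
nu = (m-1) (1 + W / ((1+1/m) B))^2, optionally shrunk by the
Barnard-Rubin small-sample adjustment when the complete-data degrees of
freedom are supplied.  Bounded metrics (AUC, proportions) are pooled on the
logit scale with delta-method variances and back-transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm, t as t_dist


class PoolingError(ValueError):
    pass


@dataclass(frozen=True)
class PooledEstimate:
    qbar: float
    within: float
    between: float
    total: float
    m: int
    ci: tuple[float, float]
    df: float
    transform: str = "identity"


def _to_transformed(x: np.ndarray, v: np.ndarray, transform: str):
    if transform == "identity":
        return x, v
    if transform == "logit":
        if ((x <= 0) | (x >= 1)).any():
            raise PoolingError("logit transform needs estimates strictly in (0,1)")
        # delta method: var(logit p) = var(p) / (p(1-p))^2
        return logit(x), v / (x * (1 - x)) ** 2
    raise PoolingError(f"unknown transform {transform!r}")


def _from_transformed(q: float, transform: str) -> float:
    return float(expit(q)) if transform == "logit" else float(q)


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    transform: str = "identity",
    level: float = 0.95,
    df_com: float | None = None,
) -> PooledEstimate:
    """Pool m estimates and their variances by Rubin's rules.

    ``df_com`` — complete-data degrees of freedom — activates the
    Barnard-Rubin adjustment; without it the large-sample Rubin df is used
    (infinite when the between-imputation variance is zero).
    """
    x = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if x.shape != v.shape:
        raise PoolingError("estimates and variances must have equal length")
    m = len(x)
    if m < 2:
        raise PoolingError("pooling requires m >= 2 imputations")
    if (v < 0).any():
        raise PoolingError("variances must be non-negative")
    q, u = _to_transformed(x, v, transform)
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between

    if between > 0:
        r = (1.0 + 1.0 / m) * between / within if within > 0 else math.inf
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2 if math.isfinite(r) else (m - 1)
        if df_com is not None:
            lam = (1.0 + 1.0 / m) * between / total
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    else:
        df = math.inf

    if total > 0:
        crit = (
            norm.ppf(0.5 + level / 2.0)
            if math.isinf(df)
            else t_dist.ppf(0.5 + level / 2.0, df)
        )
        half = crit * math.sqrt(total)
        ci = (qbar - half, qbar + half)
    else:
        ci = (qbar, qbar)
    return PooledEstimate(
        qbar=_from_transformed(qbar, transform),
        within=within,
        between=between,
        total=total,
        m=m,
        ci=(_from_transformed(ci[0], transform), _from_transformed(ci[1], transform)),
        df=float(df),
        transform=transform,
    )


#: metric name -> (pooling transform, whether a variance is available).
#: Brier and E/O are reported as simple means without a CI.
POOL_PLAN = {
    "auc": ("logit", True),
    "citl": ("identity", True),
    "slope": ("identity", True),
    "delta": ("identity", True),
    "gamma": ("identity", True),
    "sensitivity": ("logit", True),
    "specificity": ("logit", True),
    "ppv": ("logit", True),
    "npv": ("logit", True),
}


def pool_report(
    reports: Sequence[dict], df_com: float | None = None
) -> dict[str, PooledEstimate | float]:
    """Pool per-imputation performance dicts into one report.

    Each input dict carries metric values, with ``<name>_variance`` keys for
    metrics pooled with a CI.  Metrics in :data:`POOL_PLAN` are pooled by
    Rubin's rules on their declared scale; any other numeric key (brier,
    eo_ratio, expected, ...) is pooled as a simple mean.
    """
    if not reports:
        raise PoolingError("no reports to pool")
    keys = set(reports[0])
    for r in reports[1:]:
        if set(r) != keys:
            raise PoolingError("per-imputation reports carry different keys")
    pooled: dict[str, PooledEstimate | float] = {}
    for key in sorted(keys):
        if key.endswith("_variance"):
            continue
        values = [r[key] for r in reports]
        if key in POOL_PLAN:
            transform, _ = POOL_PLAN[key]
            variances = [r.get(f"{key}_variance", 0.0) for r in reports]
            pooled[key] = rubin_pool(values, variances, transform=transform, df_com=df_com)
        else:
            pooled[key] = float(np.mean(values))
    return pooled
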