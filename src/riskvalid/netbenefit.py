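"""Decision curve analysis.

Net benefit at threshold probability ``pt`` weighs true against false
positives by the threshold odds:

    NB = TP/n - (FP/n) * pt / (1 - pt)

so at pt = 0.1 a missed event counts 9x worse than an unnecessary
intervention.  The model strategy flags risk >= pt; a binary comparator
(e.g. unstructured clinical judgement) keeps fixed TP/FP while only the
weight varies; treat-all and treat-none are the closed-form baselines.
Standardised net benefit divides by the outcome prevalence, giving the
proportion of events that would receive net benefit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import ConfusionCounts, classify, counts_from_flags


class NetBenefitError(ValueError):
    pass


def net_benefit(counts: ConfusionCounts, n: int, pt: float) -> float:
    """NB = tp/n - (fp/n) * pt/(1-pt); pt must be strictly inside (0,1)."""
    if not 0.0 < pt < 1.0:
        raise NetBenefitError("threshold probability must be in (0,1)")
    return counts.tp / n - (counts.fp / n) * pt / (1.0 - pt)


def default_dca_grid() -> np.ndarray:
    """Clinically realistic preference range 0.05-0.35 in 0.01 steps."""
    return np.round(np.arange(0.05, 0.3501, 0.01), 4)


def dca_curve(probabilities, outcomes, judgement_flags=None, grid=None) -> pd.DataFrame:
    """Net benefit of model / judgement / treat-all / treat-none over a grid.

    Returns one row per threshold probability with columns ``pt``,
    ``nb_model``, ``nb_judgement`` (NaN when no flags given), ``nb_all``,
    ``nb_none`` and ``snb_model``.
    """
    y = np.asarray(outcomes, dtype=int)
    if y.min() == y.max():
        raise NetBenefitError("both outcome classes must be present")
    if grid is None:
        grid = default_dca_grid()
    grid = np.asarray(grid, dtype=float)
    if ((grid <= 0) | (grid >= 1)).any():
        raise NetBenefitError("grid must lie strictly inside (0,1)")
    n = len(y)
    prevalence = y.mean()
    judge_counts = None
    if judgement_flags is not None:
        judge_counts = counts_from_flags(judgement_flags, y)
    rows = []
    for pt in grid:
        model_counts = classify(probabilities, y, float(pt))
        nb_model = net_benefit(model_counts, n, float(pt))
        odds = pt / (1.0 - pt)
        rows.append(
            {
                "pt": float(pt),
                "nb_model": nb_model,
                "nb_judgement": (
                    net_benefit(judge_counts, n, float(pt))
                    if judge_counts is not None
                    else np.nan
                ),
                "nb_all": prevalence - (1.0 - prevalence) * odds,
                "nb_none": 0.0,
                "snb_model": nb_model / prevalence,
            }
        )
    curve = pd.DataFrame(rows)
    curve.attrs["n"] = n
    curve.attrs["prevalence"] = float(prevalence)
    return curve


def pool_dca_curves(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Average net-benefit curves across imputed datasets (simple mean)."""
    if not curves:
        raise NetBenefitError("no curves to pool")
    base = curves[0]["pt"].to_numpy()
    for c in curves[1:]:
        if not np.array_equal(c["pt"].to_numpy(), base):
            raise NetBenefitError("curves must share the same pt grid")
    stacked = pd.concat(curves).groupby("pt", as_index=False).mean()
    stacked.attrs["n"] = curves[0].attrs.get("n")
    stacked.attrs["prevalence"] = float(
        np.mean([c.attrs.get("prevalence", np.nan) for c in curves])
    )
    return stacked
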