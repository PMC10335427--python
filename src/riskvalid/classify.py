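"""Threshold classification of risk predictions and 2x2-table analysis.

Includes reconstruction of a confusion table from published marginals
(cohort size, event count, number flagged, sensitivity) — the way a
reader recovers the four cells of a clinical-judgement 2x2 table that a
study reports only through its margins and accuracy summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import ProportionCI, wilson_ci


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ClassificationError("confusion cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_events(self) -> int:
        return self.tp + self.fn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class ClassificationMetrics:
    sensitivity: ProportionCI | None
    specificity: ProportionCI | None
    ppv: ProportionCI | None
    npv: ProportionCI | None
    threshold: float | str = "judgement"


def classify(probabilities, outcomes, threshold: float) -> ConfusionCounts:
    """Tally a 2x2 table flagging individuals with risk >= threshold.

    The boundary is inclusive: a predicted risk exactly at the cut-off
    counts as high risk.
    """
    if not 0.0 <= threshold <= 1.0 + 1e-12:
        raise ClassificationError("threshold must lie in [0,1]")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    flag = p >= threshold
    return counts_from_flags(flag.astype(int), y)


def counts_from_flags(flags, outcomes) -> ConfusionCounts:
    flag = np.asarray(flags, dtype=bool)
    y = np.asarray(outcomes, dtype=int)
    return ConfusionCounts(
        tp=int((flag & (y == 1)).sum()),
        fp=int((flag & (y == 0)).sum()),
        fn=int((~flag & (y == 1)).sum()),
        tn=int((~flag & (y == 0)).sum()),
    )


def metrics_from_counts(
    counts: ConfusionCounts, threshold: float | str = "judgement"
) -> ClassificationMetrics:
    """Sens/spec/PPV/NPV with Wilson CIs; zero-denominator metrics are None."""

    def ratio(k: int, d: int) -> ProportionCI | None:
        return wilson_ci(k, d) if d > 0 else None

    return ClassificationMetrics(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        npv=ratio(counts.tn, counts.tn + counts.fn),
        threshold=threshold,
    )


def counts_from_marginals(
    n: int, n_events: int, n_flagged: int, sensitivity: float
) -> ConfusionCounts:
    """Reconstruct a 2x2 table from its published margins.

    tp = round(sensitivity * n_events) (nearest integer); the other cells
    follow by subtraction.  Raises if the margins are inconsistent.
    """
    tp = int(round(sensitivity * n_events))
    fn = n_events - tp
    fp = n_flagged - tp
    tn = n - n_events - fp
    if min(tp, fn, fp, tn) < 0:
        raise ClassificationError(
            f"inconsistent marginals: n={n}, events={n_events}, "
            f"flagged={n_flagged}, sensitivity={sensitivity}"
        )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def threshold_sweep(probabilities, outcomes, grid=None) -> pd.DataFrame:
    """Classification metrics across a grid of risk cut-offs.

    Default grid: 0.025 steps over [0.025, 0.50] (always containing the
    clinically discussed 0.10 and 0.125 cut-offs).  One row per threshold
    with the four cells, the four accuracy metrics (with CIs) and the
    number flagged high risk.
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if ((grid < 0) | (grid > 1)).any():
        raise ClassificationError("grid thresholds must lie in [0,1]")
    rows = []
    for t in grid:
        c = classify(probabilities, outcomes, float(t))
        m = metrics_from_counts(c, threshold=float(t))
        row = {
            "threshold": float(t),
            "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
            "n_flagged": c.n_flagged,
        }
        for label, ci in (
            ("sensitivity", m.sensitivity), ("specificity", m.specificity),
            ("ppv", m.ppv), ("npv", m.npv),
        ):
            row[label] = ci.estimate if ci else np.nan
            row[f"{label}_lower"] = ci.lower if ci else np.nan
            row[f"{label}_upper"] = ci.upper if ci else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(0.025, 0.5001, 0.025), 4)
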