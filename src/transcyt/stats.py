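"""Blank-corrected all-pairs fold-change statistic with a binomial null.

Per-cell fluorescence in primary endothelial cultures varies over decades
between experimental replicates, so raw intensities are not comparable
across days.  The statistic implemented here removes that variability by
working entirely in within-replicate ratios:

For replicate k with blank cells (autofluorescence), control cells and
condition cells,

    Change_cond_k = { (cond_i - mean(blank_k)) / (ctrl_j - mean(blank_k)) }
                    over all pairs (i, j),

and the n replicates are pooled into a single set Change_cond (the control
set Change_ctrl is built the same way with ctrl_i in the numerator).  The
fold change between condition and control is the cross-division of every
point of Change_cond by every point of Change_ctrl; its median, 68% band
(16th–84th percentiles) and 95% band (2.5th–97.5th) are reported.

The p-value treats each fold-change point as a sign trial against 1: with
f_fail the fraction of points contradicting the direction of the median,
the p-value is the lower binomial tail P(X <= round(f_fail * n_trial)) for
X ~ Binomial(n_trial, 1/2).  Because the all-pairs points are not
independent, n_trial is not the number of points but the number of
independent condition cells, sum over replicates of Ncells_cond.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceDataset",
    "ChangeSet",
    "FoldChangePoints",
    "FoldChangeSummary",
    "change_set",
    "pairwise_fold_change",
    "binomial_p_value",
    "summarize",
    "fold_reduction_display",
]

CROSS_CAP_DEFAULT = 10 ** 6


@dataclass
class FluorescenceDataset:
    """Per-replicate blank / control / condition per-cell measurements.

    ``blank[k]``, ``ctrl[k]`` are arrays of per-cell values for replicate
    k; ``conditions[label][k]`` the condition cells.  Constructed directly
    or from a tidy table via :meth:`from_frame`.
    """

    blank: dict[int, np.ndarray]
    ctrl: dict[int, np.ndarray]
    conditions: dict[str, dict[int, np.ndarray]]

    def __post_init__(self) -> None:
        total_blank = sum(len(v) for v in self.blank.values())
        if total_blank < 1:
            raise ValueError("need at least one blank cell overall")
        for k in self.ctrl:
            if k not in self.blank:
                raise ValueError(f"replicate {k} has ctrl cells but no blank cells")

    @property
    def replicates(self) -> list[int]:
        return sorted(self.ctrl)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FluorescenceDataset":
        """Build from a tidy table with columns
        ``replicate_id, group, condition_label, value``."""
        required = {"replicate_id", "group", "condition_label", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        blank: dict[int, np.ndarray] = {}
        ctrl: dict[int, np.ndarray] = {}
        conditions: dict[str, dict[int, np.ndarray]] = {}
        for (k, group, label), sub in df.groupby(
                ["replicate_id", "group", "condition_label"], sort=True):
            vals = sub["value"].to_numpy(dtype=float)
            k = int(k)
            if group == "blank":
                blank[k] = vals
            elif group == "ctrl":
                ctrl[k] = vals
            elif group == "cond":
                conditions.setdefault(str(label), {})[k] = vals
            else:
                raise ValueError(f"unknown group {group!r}")
        return cls(blank, ctrl, conditions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.blank.items():
            rows.append(pd.DataFrame({"replicate_id": k, "group": "blank",
                                      "condition_label": "blank", "value": v}))
        for k, v in self.ctrl.items():
            rows.append(pd.DataFrame({"replicate_id": k, "group": "ctrl",
                                      "condition_label": "ctrl", "value": v}))
        for label, per_rep in self.conditions.items():
            for k, v in per_rep.items():
                rows.append(pd.DataFrame({"replicate_id": k, "group": "cond",
                                          "condition_label": label, "value": v}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class ChangeSet:
    """Pooled within-replicate blank-corrected ratios for one group.

    ``values`` holds every (numerator cell, control cell) ratio across all
    replicates; ``replicate_ids`` records each value's replicate of origin.
    ``n_cells_numerator`` maps replicate -> number of numerator cells used
    (the basis of the n_trial correction).  Pairs whose blank-corrected
    denominator was not positive are excluded and counted in
    ``n_excluded_pairs``.
    """

    values: np.ndarray
    replicate_ids: np.ndarray
    n_cells_numerator: dict[int, int] = field(default_factory=dict)
    n_excluded_pairs: int = 0

    @property
    def n_all(self) -> int:
        return len(self.values)

    @property
    def n_trial(self) -> int:
        return sum(self.n_cells_numerator.values())


@dataclass
class FoldChangePoints:
    points: np.ndarray
    median: float
    band68: tuple[float, float]
    band95: tuple[float, float]
    exact: bool   # False when the cross-division was subsampled


@dataclass
class FoldChangeSummary:
    condition_label: str
    median: float
    band68: tuple[float, float]
    band95: tuple[float, float]
    direction: str            # increase | decrease | none
    f_fail: float
    n_trial: int
    p_value: float
    fold_reduction: float     # 1 / median
    log2_median: float
    n_points: int
    exact: bool

    def report(self) -> dict:
        """Rounded values as printed in reports: medians and log2 to 2 dp,
        fold reduction via :func:`fold_reduction_display`."""
        return {
            "condition": self.condition_label,
            "median_fold_change": round(self.median, 2),
            "fold_reduction": fold_reduction_display(self.median),
            "log2_median": round(self.log2_median, 2),
            "band68": [round(v, 3) for v in self.band68],
            "band95": [round(v, 3) for v in self.band95],
            "direction": self.direction,
            "f_fail": self.f_fail,
            "n_trial": self.n_trial,
            "p_value": self.p_value,
        }


def fold_reduction_display(median: float) -> float:
    """Fold reduction (1/median) rounded for display.

    Below 2 the value is shown to two decimals, at or above 2 to one
    (1/0.51 -> 1.96, 1/0.347 -> 2.9).
    """
    fold = 1.0 / median
    return round(fold, 2) if fold < 2 else round(fold, 1)


def change_set(dataset: FluorescenceDataset, condition_label: str) -> ChangeSet:
    """Build the pooled Change set for a condition (or for the control).

    Pass ``condition_label="ctrl"`` for Change_ctrl, in which case the
    numerator cells are the control cells themselves (including i = j
    pairs, which makes the control set inversion-symmetric with median
    exactly 1).  Pairs with a non-positive blank-corrected denominator are
    excluded and counted.
    """
    values: list[np.ndarray] = []
    rep_ids: list[np.ndarray] = []
    n_cells: dict[int, int] = {}
    n_excluded = 0
    for k in dataset.replicates:
        if condition_label == "ctrl":
            numerator_cells = dataset.ctrl[k]
        else:
            per_rep = dataset.conditions.get(condition_label, {})
            if k not in per_rep:
                continue
            numerator_cells = per_rep[k]
        ctrl_cells = dataset.ctrl[k]
        if len(numerator_cells) < 1 or len(ctrl_cells) < 1:
            raise ValueError(f"replicate {k} needs >= 1 condition and >= 1 ctrl cell")
        blank_mean = float(np.mean(dataset.blank[k]))
        num = np.asarray(numerator_cells, dtype=float) - blank_mean
        den = np.asarray(ctrl_cells, dtype=float) - blank_mean
        good = den > 0
        n_excluded += int((~good).sum()) * len(num)
        ratios = np.outer(num, den[good] ** -1.0).ravel()
        values.append(ratios)
        rep_ids.append(np.full(len(ratios), k))
        n_cells[k] = len(num)
    if not values:
        raise ValueError(f"no replicates carry condition {condition_label!r}")
    if n_excluded:
        logger.warning("excluded %d pairs with non-positive blank-corrected "
                       "denominators", n_excluded)
    return ChangeSet(np.concatenate(values), np.concatenate(rep_ids),
                     n_cells, n_excluded)


def pairwise_fold_change(cond_set: ChangeSet, ctrl_set: ChangeSet,
                         cap: int = CROSS_CAP_DEFAULT,
                         rng: np.random.Generator | int | None = 0) -> FoldChangePoints:
    """All-pairs fold change between a condition and the control set.

    Every point of the condition Change set is divided by every point of
    the control Change set.  The full cross-division is evaluated exactly
    when its size is at most ``cap``; above the cap, ``cap`` pairs are
    drawn uniformly (seeded) instead.  Returns the points with their
    median and the 68% / 95% percentile bands.
    """
    c, d = cond_set.values, ctrl_set.values
    if len(c) == 0 or len(d) == 0:
        raise ValueError("empty Change set")
    n_total = len(c) * len(d)
    if n_total <= cap:
        points = np.outer(c, d ** -1.0).ravel()
        exact = True
    else:
        rng = np.random.default_rng(rng)
        ii = rng.integers(0, len(c), cap)
        jj = rng.integers(0, len(d), cap)
        points = c[ii] / d[jj]
        exact = False
    q = np.percentile(points, [2.5, 16, 50, 84, 97.5])
    return FoldChangePoints(points, float(q[2]), (float(q[1]), float(q[3])),
                            (float(q[0]), float(q[4])), exact)


def binomial_p_value(fold_points: np.ndarray, direction: str, n_trial: int,
                     mode: str = "tail") -> tuple[float, float]:
    """Sign-test binomial p-value for a fold-change point set.

    ``f_fail`` is the fraction of points contradicting ``direction``
    (points <= 1 for an increase, >= 1 for a decrease).  The p-value is
    P(X <= k) for X ~ Binomial(n_trial, 1/2) with k = round(f_fail *
    n_trial); ``mode="pmf"`` instead returns the probability mass at k.
    ``direction="none"`` (median exactly 1) returns p = 1 by convention.

    Returns ``(p_value, f_fail)``.
    """
    if n_trial < 1:
        raise ValueError("n_trial must be >= 1")
    fold_points = np.asarray(fold_points, dtype=float)
    if direction == "increase":
        f_fail = float(np.mean(fold_points <= 1.0))
    elif direction == "decrease":
        f_fail = float(np.mean(fold_points >= 1.0))
    elif direction == "none":
        return 1.0, float(np.mean(fold_points >= 1.0))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    k = int(math.floor(f_fail * n_trial + 0.5))
    if mode == "tail":
        p = float(binom.cdf(k, n_trial, 0.5))
    elif mode == "pmf":
        p = float(binom.pmf(k, n_trial, 0.5))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(min(max(p, 0.0), 1.0)), f_fail


def summarize(dataset: FluorescenceDataset, condition_label: str,
              cap: int = CROSS_CAP_DEFAULT,
              rng: np.random.Generator | int | None = 0,
              p_mode: str = "tail") -> FoldChangeSummary:
    """Full condition-vs-control inference for one condition label.

    Composes :func:`change_set` (condition and control),
    :func:`pairwise_fold_change` and :func:`binomial_p_value`; also reports
    the fold reduction (1/median) and log2 median.  ``n_trial`` is the sum
    over replicates of condition-cell counts.
    """
    cond = change_set(dataset, condition_label)
    ctrl = change_set(dataset, "ctrl")
    fc = pairwise_fold_change(cond, ctrl, cap=cap, rng=rng)
    if fc.median > 1:
        direction = "increase"
    elif fc.median < 1:
        direction = "decrease"
    else:
        direction = "none"
    p, f_fail = binomial_p_value(fc.points, direction, cond.n_trial, mode=p_mode)
    return FoldChangeSummary(
        condition_label=condition_label,
        median=fc.median,
        band68=fc.band68,
        band95=fc.band95,
        direction=direction,
        f_fail=f_fail,
        n_trial=cond.n_trial,
        p_value=p,
        fold_reduction=1.0 / fc.median,
        log2_median=float(np.log2(fc.median)),
        n_points=len(fc.points),
        exact=fc.exact,
    )
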