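"""Validation-side metrics: confusion counts, stratified error tables,
conformal validity curves, quintile fractions and population projections.

"Undecided" point labels count as errors for both classes — conservative,
and consistent with reporting a binary disease status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .conformal import CASE, CONTROL

__all__ = [
    "ConfusionCounts",
    "ProjectionInput",
    "DEFAULT_AGE_BINS",
    "DEFAULT_MIN_STRATUM",
    "confusion_metrics",
    "stratified_error_rates",
    "validity_curve",
    "quintile_fraction",
    "population_projection",
]

#: Default age bins: [50, 60], (60, 70], (70, 80], (80, 95].
DEFAULT_AGE_BINS = (50.0, 60.0, 70.0, 80.0, 95.0)

#: Smallest stratum size reported without a small-sample flag.
DEFAULT_MIN_STRATUM = 73


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ProjectionInput:
    fraction: float
    base_count: int
    description: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.base_count < 0:
            raise ValueError("base_count must be non-negative")


def confusion_metrics(
    predictions: Sequence[str], truth: Sequence[str]
) -> tuple[float, float, ConfusionCounts]:
    """Sensitivity, specificity and raw counts from point labels.

    Sensitivity = tp / (tp + fn); specificity = tn / (tn + fp).
    Undecided predictions are wrong for whichever class they face. A
    class absent from the truth makes its metric undefined (NaN), never 0.
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    is_case = true == CASE
    is_control = true == CONTROL
    if not np.all(is_case | is_control):
        bad = sorted(set(true.tolist()) - {CASE, CONTROL})
        raise ValueError(f"unknown truth labels: {bad}")
    tp = int(np.sum(is_case & (pred == CASE)))
    fn = int(np.sum(is_case & (pred != CASE)))
    tn = int(np.sum(is_control & (pred == CONTROL)))
    fp = int(np.sum(is_control & (pred != CONTROL)))
    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    return sens, spec, ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _age_bin_labels(edges: Sequence[float]) -> list[str]:
    labels = [f"[{edges[0]:g},{edges[1]:g}]"]
    labels += [f"({edges[i]:g},{edges[i + 1]:g}]" for i in range(1, len(edges) - 1)]
    return labels


def _bin_ages(ages: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    # First bin is closed on both sides; subsequent bins are (lo, hi].
    idx = np.searchsorted(np.asarray(edges[1:]), ages, side="left")
    idx = np.clip(idx, 0, len(edges) - 2)
    return idx


def stratified_error_rates(
    predictions: Sequence[str],
    truth: Sequence[str],
    risk_groups: Sequence[int],
    ages: Sequence[float],
    sexes: Sequence[str],
    age_bins: Sequence[float] = DEFAULT_AGE_BINS,
    min_n: int = DEFAULT_MIN_STRATUM,
    pool_groups: bool = True,
    pool_sexes: bool = False,
) -> pd.DataFrame:
    """Empirical point-prediction error per risk group x age bin x sex.

    With ``pool_groups`` the middle and high risk groups are pooled as
    "2-3" and "4-5" (group 1 and 5 retain their own rows as the extremes
    of interest; pooling follows the common reporting layout). Strata
    smaller than ``min_n`` are flagged; empty strata keep n = 0 and an
    undefined (NaN) error rate.
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    groups = np.asarray(risk_groups, dtype=int)
    ages_arr = np.asarray(ages, dtype=float)
    sexes_arr = np.asarray(sexes)
    n = pred.shape[0]
    if not (true.shape[0] == groups.shape[0] == ages_arr.shape[0] == sexes_arr.shape[0] == n):
        raise ValueError("all input vectors must have equal length")
    if ages_arr.size and (ages_arr.min() < age_bins[0] or ages_arr.max() > age_bins[-1]):
        raise ValueError("age bins do not cover the cohort age range")

    wrong = pred != true
    bin_idx = _bin_ages(ages_arr, age_bins)
    bin_labels = _age_bin_labels(age_bins)

    if pool_groups:
        group_keys = [("1", groups == 1), ("2-3", np.isin(groups, (2, 3))),
                      ("4-5", np.isin(groups, (4, 5)))]
    else:
        group_keys = [(str(g), groups == g) for g in range(1, 6)]
    sex_keys = [("all", np.ones(n, dtype=bool))] if pool_sexes else [
        (s, sexes_arr == s) for s in sorted(set(sexes_arr.tolist()))
    ]

    rows = []
    for g_label, g_mask in group_keys:
        for b, b_label in enumerate(bin_labels):
            b_mask = bin_idx == b
            for s_label, s_mask in sex_keys:
                mask = g_mask & b_mask & s_mask
                size = int(mask.sum())
                rate = float(wrong[mask].mean()) if size else math.nan
                rows.append(
                    {
                        "risk_group": g_label,
                        "age_bin": b_label,
                        "sex": s_label,
                        "n": size,
                        "error_rate": rate,
                        "flagged_small": size < min_n,
                    }
                )
    return pd.DataFrame(rows)


def validity_curve(
    p_values: dict[str, np.ndarray] | pd.DataFrame,
    truth: Sequence[str],
    eps_grid: Sequence[float],
) -> pd.DataFrame:
    """Empirical class-conditional error of the conformal p-values.

    ``empirical_error(eps, class)`` is the fraction of class members
    whose true-label p-value is <= eps — i.e. whose prediction set at
    significance eps excludes the truth.
    """
    eps_arr = np.asarray(eps_grid, dtype=float)
    if eps_arr.size and (eps_arr.min() <= 0.0 or eps_arr.max() >= 1.0):
        raise ValueError("eps grid must lie strictly inside (0, 1)")
    true = np.asarray(truth)
    p_case = np.asarray(p_values["p_case"], dtype=float)
    p_control = np.asarray(p_values["p_control"], dtype=float)
    p_true = np.where(true == CASE, p_case, p_control)
    rows = []
    for eps in eps_arr:
        for label in (CONTROL, CASE):
            members = true == label
            err = float((p_true[members] <= eps).mean()) if members.any() else math.nan
            rows.append({"epsilon": float(eps), "class": label, "empirical_error": err,
                         "n": int(members.sum())})
    return pd.DataFrame(rows)


def quintile_fraction(risk_groups: Sequence[int], groups_of_interest=(4, 5)) -> float:
    """Fraction of a cohort falling into the given risk groups."""
    groups = np.asarray(risk_groups, dtype=int)
    if groups.size == 0:
        raise ValueError("cohort must be non-empty")
    return float(np.isin(groups, tuple(groups_of_interest)).mean())


def population_projection(inp: ProjectionInput) -> int:
    """Project a stratum fraction onto a population count (nearest integer)."""
    return int(round(inp.fraction * inp.base_count))
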