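"""Scoring of driver-gene predictions against curated truth sets.

AUC is computed rank-based (Mann-Whitney statistic) with ties counted
half, so it agrees exactly with pair counting.  Units with a single
class (e.g. a patient whose altered genes are all known drivers) have
an undefined AUC, reported as NaN and excluded from medians but counted
in a degenerate tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EvaluationResult",
    "PersonalizedSummary",
    "roc_auc",
    "evaluate_batch",
    "evaluate_personalized",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Scores for one unit (a dataset or a patient).

    ``auc`` is NaN when only one class is present; the percentage fields
    are NaN when no gene was called driver.
    """

    unit: str
    auc: float
    n_predicted_drivers: int
    pct_true_drivers: float
    pct_actionable: float

    def __post_init__(self) -> None:
        if self.n_predicted_drivers < 0:
            raise ValueError("n_predicted_drivers must be >= 0")
        for pct in (self.pct_true_drivers, self.pct_actionable):
            if not math.isnan(pct) and not 0 <= pct <= 100:
                raise ValueError("percentages must lie in [0, 100]")


@dataclass(frozen=True)
class PersonalizedSummary:
    """Cross-patient summary of per-patient evaluations."""

    median_auc: float
    n_patients: int
    n_degenerate: int  # patients with undefined (single-class) AUC


def roc_auc(scores: Sequence[float], truth_labels: Sequence[bool]) -> float:
    """Rank-based AUC with ties counted 1/2 (Mann-Whitney statistic).

    Returns NaN when either class is absent, matching the degenerate
    per-patient cases where every altered gene is (or none is) a known
    driver.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(truth_labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and truth_labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    rank_sum_pos = ranks[labels].sum()
    u_statistic = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u_statistic / (n_pos * n_neg))


def evaluate_batch(
    predictions: pd.DataFrame,
    truth_set: Iterable[str],
    actionable_set: Iterable[str],
    threshold: float,
    unit: str = "batch",
) -> EvaluationResult:
    """Evaluate ranked gene predictions for one dataset.

    ``predictions`` needs columns ``gene`` and ``probability`` (one row
    per gene).  AUC treats truth-set membership as the positive label
    over all scored genes; the driver call at ``threshold`` is
    probability >= threshold (inclusive), and the percentage columns are
    computed among called genes.
    """
    if predictions.empty:
        raise ValueError("predictions must cover at least one gene")
    truth = set(truth_set)
    actionable = set(actionable_set)
    genes = predictions["gene"].to_numpy()
    probs = predictions["probability"].to_numpy(dtype=float)
    labels = np.array([g in truth for g in genes])

    auc = roc_auc(probs, labels)
    called = probs >= threshold
    n_called = int(called.sum())
    if n_called == 0:
        pct_true = pct_act = float("nan")
    else:
        called_genes = genes[called]
        pct_true = 100.0 * sum(g in truth for g in called_genes) / n_called
        pct_act = 100.0 * sum(g in actionable for g in called_genes) / n_called
    return EvaluationResult(
        unit=unit,
        auc=auc,
        n_predicted_drivers=n_called,
        pct_true_drivers=pct_true,
        pct_actionable=pct_act,
    )


def evaluate_personalized(
    per_patient_predictions: Mapping[str, pd.DataFrame],
    truth_set: Iterable[str],
    actionable_set: Iterable[str],
    threshold: float | Mapping[str, float],
) -> tuple[list[EvaluationResult], PersonalizedSummary]:
    """Evaluate each patient's predictions and summarize across patients.

    ``threshold`` is either a single cutoff or a per-patient mapping.
    Patients with undefined AUC are excluded from the median and counted
    as degenerate.
    """
    truth = set(truth_set)
    actionable = set(actionable_set)
    results: list[EvaluationResult] = []
    for patient_id in sorted(per_patient_predictions):
        thr = (
            threshold[patient_id]
            if isinstance(threshold, Mapping)
            else float(threshold)
        )
        results.append(
            evaluate_batch(
                per_patient_predictions[patient_id], truth, actionable, thr,
                unit=patient_id,
            )
        )
    defined = [r.auc for r in results if not math.isnan(r.auc)]
    summary = PersonalizedSummary(
        median_auc=float(np.median(defined)) if defined else float("nan"),
        n_patients=len(results),
        n_degenerate=len(results) - len(defined),
    )
    return results, summary
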