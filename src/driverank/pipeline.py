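"""End-to-end orchestration: cohort tables -> features -> model -> ranking.

This is thin glue over the other modules: build one feature matrix per
cancer type (tasks share the gene universe and differ in their prior
gene-score table), label genes by truth-set membership, split genes
into train / validation / test partitions stratified by label, fit the
sparse multi-task model, pick per-task thresholds on the validation
genes, and score the held-out genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import roc_auc
from .feature_builder import FeatureBuildConfig, build_feature_matrix, build_personalized_features
from .io_formats import ContractError
from .metapredictor import MetapredictorModel
from .mtl_model import (
    DEFAULT_LAMBDA1,
    DEFAULT_LAMBDA2,
    MTLConfig,
    MTLModel,
    TaskDataset,
    fit_mtl,
    predict_probability,
    select_task_thresholds,
)
from .synthetic_fixtures import CohortFixture

__all__ = ["CohortAnalysis", "build_task_features", "run_cohort_analysis",
           "personalized_predictions"]


@dataclass
class CohortAnalysis:
    """Everything produced by one batch run."""

    model: MTLModel
    feature_frames: dict[str, pd.DataFrame]  # task -> genes x 26
    train_genes: list[str]
    validation_genes: list[str]
    test_genes: list[str]
    test_predictions: dict[str, pd.DataFrame]  # task -> (gene, probability)
    test_auc: dict[str, float]
    pooled_test_auc: float


def build_task_features(
    fixture: CohortFixture,
    metapredictor: MetapredictorModel,
    feature_config: FeatureBuildConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """One genes x 26 feature frame per cancer type."""
    return {
        task: build_feature_matrix(
            fixture.variants,
            fixture.segments,
            fixture.genes,
            fixture.mcr_regions,
            fixture.prior_scores[task],
            fixture.pathways,
            metapredictor,
            feature_config,
        )
        for task in fixture.task_names
    }


def _stratified_gene_split(
    genes: list[str], labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    first: list[str] = []
    second: list[str] = []
    for cls in (False, True):
        members = [g for g, lab in zip(genes, labels) if lab == cls]
        rng.shuffle(members)
        n_first = round(fraction * len(members))
        first.extend(members[:n_first])
        second.extend(members[n_first:])
    return sorted(first), sorted(second)


def run_cohort_analysis(
    fixture: CohortFixture,
    metapredictor: MetapredictorModel,
    feature_config: FeatureBuildConfig | None = None,
    mtl_config: MTLConfig | None = None,
    lambda1: float = DEFAULT_LAMBDA1,
    lambda2: float = DEFAULT_LAMBDA2,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> CohortAnalysis:
    """Train on a gene split and score the held-out genes per task.

    Genes are split train/test by ``train_fraction`` stratified on
    truth-set membership; the training genes are sub-split 75/25 into
    fitting and validation genes (validation drives the per-task
    thresholds).  AUC uses truth membership as labels on the held-out
    genes, per task and pooled.
    """
    frames = build_task_features(fixture, metapredictor, feature_config)
    universe = list(next(iter(frames.values())).index)
    truth_labels = np.array([g in fixture.truth_genes for g in universe])
    if truth_labels.all() or not truth_labels.any():
        raise ContractError("gene universe must contain both driver and passenger genes")

    rng = np.random.default_rng(seed)
    train_genes, test_genes = _stratified_gene_split(
        universe, truth_labels, train_fraction, rng
    )
    label_of = dict(zip(universe, truth_labels))
    fit_genes, valid_genes = _stratified_gene_split(
        train_genes, np.array([label_of[g] for g in train_genes]), 0.75, rng
    )

    def subset(task: str, genes: list[str]) -> TaskDataset:
        frame = frames[task].loc[genes]
        y = np.where([label_of[g] for g in genes], 1.0, -1.0)
        return TaskDataset(task, frame.to_numpy(), y)

    feature_order = tuple(next(iter(frames.values())).columns)
    fit_tasks = [subset(task, fit_genes) for task in fixture.task_names]
    model = fit_mtl(
        fit_tasks, lambda1, lambda2, config=mtl_config, feature_order=feature_order,
        seed=seed,
    )
    valid_tasks = [subset(task, valid_genes) for task in fixture.task_names]
    select_task_thresholds(model, valid_tasks)

    test_predictions: dict[str, pd.DataFrame] = {}
    test_auc: dict[str, float] = {}
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for task in fixture.task_names:
        frame = frames[task].loc[test_genes]
        probs = predict_probability(model, frame.to_numpy(), task)
        labels = np.array([label_of[g] for g in test_genes])
        order = np.argsort(-probs, kind="stable")
        test_predictions[task] = pd.DataFrame(
            {"gene": np.array(test_genes)[order], "probability": probs[order]}
        )
        test_auc[task] = roc_auc(probs, labels)
        pooled_scores.append(probs)
        pooled_labels.append(labels)
    pooled = roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))

    return CohortAnalysis(
        model=model,
        feature_frames=frames,
        train_genes=train_genes,
        validation_genes=valid_genes,
        test_genes=test_genes,
        test_predictions=test_predictions,
        test_auc=test_auc,
        pooled_test_auc=pooled,
    )


def personalized_predictions(
    fixture: CohortFixture,
    model: MTLModel,
    metapredictor: MetapredictorModel,
    task_name: str,
    feature_config: FeatureBuildConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-patient driver probabilities over each patient's altered genes."""
    patients = sorted(
        {v.patient_id for v in fixture.variants if v.patient_id is not None}
    )
    out: dict[str, pd.DataFrame] = {}
    for patient in patients:
        frame = build_personalized_features(
            fixture.variants,
            fixture.segments,
            fixture.genes,
            fixture.mcr_regions,
            fixture.prior_scores[task_name],
            fixture.pathways,
            metapredictor,
            patient,
            feature_config,
        )
        probs = predict_probability(model, frame.to_numpy(), task_name)
        out[patient] = pd.DataFrame({"gene": frame.index, "probability": probs})
    return out
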