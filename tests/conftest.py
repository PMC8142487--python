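"""Shared fixtures: cheap deterministic models and variant factories."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from driverank.io_formats import (
    PREDICTOR_NAMES,
    AnnotatedVariant,
    Consequence,
    GeneInterval,
    PathwayGeneSets,
)
from driverank.metapredictor import (
    CVConfig,
    MetapredictorModel,
    prepare_training_set,
    stratified_split,
    train_metapredictor,
)
from driverank.synthetic_fixtures import SimulationConfig, simulate_metapredictor_data

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


class FirstScoreEstimator:
    """Stub classifier whose positive probability is the first score, clipped.

    Lets feature-builder tests dictate the metaprediction probability of
    a variant directly through its SIFT slot.
    """

    classes_ = np.array([0, 1])

    def predict_proba(self, X):
        p = np.clip(np.asarray(X, dtype=float)[:, 0], 0.0, 1.0)
        return np.column_stack([1.0 - p, p])


@pytest.fixture(scope="session")
def stub_metapredictor() -> MetapredictorModel:
    return MetapredictorModel(family="stub", estimator=FirstScoreEstimator())


def make_variant(
    gene: str = "G1",
    consequence: Consequence = Consequence.CODING_NONSYNONYMOUS,
    score: float | None = 0.5,
    scores: dict[str, float | None] | None = None,
    phred: float | None = None,
    occurrence: int | None = 0,
    patient: str | None = None,
    chrom: str = "chr1",
    pos: int = 100,
) -> AnnotatedVariant:
    """A variant whose metaprediction probability (under the stub) is `score`."""
    base: dict[str, float | None] = {name: 0.5 for name in PREDICTOR_NAMES}
    base["SIFT"] = score
    if scores:
        base.update(scores)
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="T",
        gene=gene,
        consequence=consequence,
        predictor_scores=base,
        phred_noncoding=phred,
        occurrence=occurrence,
        patient_id=patient,
    )


def make_gene(gene: str, chrom: str = "chr1", start: int = 0, length: int = 10_000) -> GeneInterval:
    return GeneInterval(gene=gene, chrom=chrom, start=start, end=start + length)


def make_pathways(memberships: dict[int, set[str]] | None = None) -> PathwayGeneSets:
    """21 pathway sets, empty except for the given index -> genes map."""
    memberships = memberships or {}
    names = tuple(f"pw{i:02d}" for i in range(21))
    sets = tuple(frozenset(memberships.get(i, set())) for i in range(21))
    return PathwayGeneSets(names=names, sets=sets)


@pytest.fixture(scope="session")
def trained_metapredictor() -> MetapredictorModel:
    """A real random-forest metapredictor on the synthetic benchmark.

    Trained once per session with a light CV scheme to keep the suite
    fast; tests needing the full selection protocol train their own.
    """
    table = simulate_metapredictor_data(SimulationConfig(seed=7))
    rows = [
        (
            tuple(
                None if np.isnan(v) else float(v)
                for v in row[list(PREDICTOR_NAMES)]
            ),
            row["label"],
        )
        for _, row in table.iterrows()
    ]
    dataset = prepare_training_set(rows)
    train, _ = stratified_split(dataset, 0.75, seed=7)
    return train_metapredictor(
        train, "random_forest", CVConfig(folds=3, repeats=1), seed=7
    )
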