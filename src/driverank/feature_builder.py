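"""Gene-level feature engineering: the 26-feature vector per gene.

Feature order (frozen, serialized with every downstream model):

1. ``max_coding_impact`` — max metapredictor probability over the gene's
   coding variants with complete predictor scores
2. ``max_noncoding_impact`` — max Phred-scaled deleteriousness score
   over the gene's non-coding variants
3. ``scna_proxy_density`` — SCNA density (events/Mb) of a
   direction-matched minimal common region overlapping the gene
4. ``hotspot_or_double_hit`` — binary: recurrent (hotspot) mutation or
   non-synonymous mutation plus homozygous copy loss
5. ``prior_gene_score`` — cancer-type-specific prior association score
   (phenotype-based gene analyzer output, consumed as input)
6-26. binary membership in each of the 21 cancer-related pathways

Thresholds follow the published defaults: a segment must cover at least
25% of a gene for a gene-level SCNA call (non-strict), calls with
|log2 ratio| < 0.25 are dropped, a hotspot needs occurrence strictly
greater than 5, and homozygous loss means log2 ratio strictly below -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import (
    AnnotatedVariant,
    Consequence,
    ContractError,
    GeneInterval,
    MCRDirection,
    MCRRegion,
    PathwayGeneSets,
    SCNASegment,
)
from .metapredictor import MetapredictorModel, predict_impact_batch

__all__ = [
    "FeatureBuildConfig",
    "GeneSCNACall",
    "BASE_FEATURE_NAMES",
    "feature_names",
    "max_coding_impact",
    "max_noncoding_impact",
    "call_gene_level_scna",
    "scna_proxy_score",
    "flag_hotspot_or_double_hit",
    "pathway_membership",
    "build_feature_matrix",
    "build_personalized_features",
]

BASE_FEATURE_NAMES: tuple[str, ...] = (
    "max_coding_impact",
    "max_noncoding_impact",
    "scna_proxy_density",
    "hotspot_or_double_hit",
    "prior_gene_score",
)

_SEX_CHROMS = {"X", "Y"}


@dataclass(frozen=True)
class FeatureBuildConfig:
    """Thresholds and fill rules for feature construction.

    ``overlap_fraction``: minimum fraction of the gene's length a
    segment must cover for a gene-level SCNA call (non-strict, >=).
    ``log2_amplitude_min``: calls with |log2| below this are dropped
    (strict <).  ``hotspot_occurrence_min_exclusive``: occurrence must
    exceed this (strict >) to count as a hotspot.
    ``homozygous_loss_log2_max_exclusive``: gene log2 strictly below
    this counts as homozygous loss.  ``missing_fill`` replaces score
    features for genes without evidence.  ``double_hit_same_patient``:
    in batch mode, require the non-synonymous mutation and the copy loss
    to come from the same patient (off by default: any-patient
    conjunction across the cohort).
    """

    overlap_fraction: float = 0.25
    log2_amplitude_min: float = 0.25
    hotspot_occurrence_min_exclusive: int = 5
    homozygous_loss_log2_max_exclusive: float = -1.0
    missing_fill: float = 0.0
    double_hit_same_patient: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.overlap_fraction <= 1:
            raise ContractError("overlap_fraction must be in (0, 1]")
        for value in (self.log2_amplitude_min, self.homozygous_loss_log2_max_exclusive):
            if not np.isfinite(value):
                raise ContractError("thresholds must be finite")


@dataclass(frozen=True)
class GeneSCNACall:
    """A gene-level SCNA event: the max-|log2| segment ratio for the gene."""

    gene: str
    log2_ratio: float
    patient_id: str | None = None

    @property
    def direction(self) -> MCRDirection:
        return (
            MCRDirection.AMPLIFICATION
            if self.log2_ratio > 0
            else MCRDirection.DELETION
        )


def feature_names(pathway_sets: PathwayGeneSets) -> list[str]:
    """The canonical 26 feature column names, pathway names included."""
    return list(BASE_FEATURE_NAMES) + [f"pathway_{name}" for name in pathway_sets.names]


def _is_sex_chrom(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() in _SEX_CHROMS


def max_coding_impact(
    variants: Sequence[AnnotatedVariant],
    metapredictor: MetapredictorModel,
    config: FeatureBuildConfig | None = None,
) -> dict[str, float]:
    """Per-gene maximum metaprediction probability over coding variants.

    Only coding variants with all 12 predictor scores present are
    scorable; genes without any scorable coding variant receive the
    configured fill value.
    """
    config = config or FeatureBuildConfig()
    coding = [v for v in variants if v.consequence.is_coding and v.has_complete_scores]
    if not coding:
        return {}
    X = np.array([[v.predictor_scores[n] for n in metapredictor.feature_order]
                  for v in coding], dtype=float)
    probs = predict_impact_batch(metapredictor, X)
    best: dict[str, float] = {}
    for v, prob in zip(coding, probs):
        best[v.gene] = max(best.get(v.gene, config.missing_fill), float(prob))
    return best


def max_noncoding_impact(
    variants: Sequence[AnnotatedVariant],
    config: FeatureBuildConfig | None = None,
) -> dict[str, float]:
    """Per-gene maximum Phred-scaled score over non-coding variants."""
    config = config or FeatureBuildConfig()
    best: dict[str, float] = {}
    for v in variants:
        if v.consequence.is_coding or v.phred_noncoding is None:
            continue
        best[v.gene] = max(best.get(v.gene, config.missing_fill), v.phred_noncoding)
    return best


def call_gene_level_scna(
    segments: Sequence[SCNASegment],
    gene_model: Sequence[GeneInterval],
    config: FeatureBuildConfig | None = None,
    per_patient: bool = False,
) -> list[GeneSCNACall]:
    """Call gene-level SCNA events from segment-level data.

    A gene is called when some segment covers at least
    ``overlap_fraction`` of the gene's length; the call's log2 ratio is
    that of the qualifying segment with maximum |log2| (ties broken by
    genomic order of segments).  Calls with |log2| below
    ``log2_amplitude_min`` are dropped, and genes on sex chromosomes are
    excluded.  With ``per_patient`` the procedure runs within each
    patient's segments separately.
    """
    config = config or FeatureBuildConfig()
    if not gene_model:
        raise ContractError("gene model is empty")

    groups: dict[str | None, list[SCNASegment]]
    if per_patient:
        groups = {}
        for s in segments:
            groups.setdefault(s.patient_id, []).append(s)
    else:
        groups = {None: list(segments)}

    calls: list[GeneSCNACall] = []
    for patient_id, group in groups.items():
        trees: dict[str, IntervalTree] = {}
        for order, s in enumerate(group):
            trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, (order, s))
        for gene in gene_model:
            if _is_sex_chrom(gene.chrom):
                continue
            tree = trees.get(gene.chrom)
            if tree is None:
                continue
            best: SCNASegment | None = None
            best_key: tuple[float, int] | None = None
            for iv in tree.overlap(gene.start, gene.end):
                order, seg = iv.data
                overlap = min(seg.end, gene.end) - max(seg.start, gene.start)
                if overlap / gene.length < config.overlap_fraction:
                    continue
                # max |log2| wins; earlier genomic order wins ties
                key = (abs(seg.log2_ratio), -order)
                if best_key is None or key > best_key:
                    best, best_key = seg, key
            if best is None or abs(best.log2_ratio) < config.log2_amplitude_min:
                continue
            calls.append(
                GeneSCNACall(
                    gene=gene.gene,
                    log2_ratio=best.log2_ratio,
                    patient_id=patient_id if per_patient else best.patient_id,
                )
            )
    return calls


def scna_proxy_score(
    calls: Sequence[GeneSCNACall],
    mcr_regions: Sequence[MCRRegion],
    gene_model: Sequence[GeneInterval],
) -> dict[str, float]:
    """Assign each called gene the density of a direction-matched MCR.

    A gene scores the SCNA density (events/Mb) of an overlapping minimal
    common region whose direction (amplification/deletion) matches the
    sign of the gene's log2 ratio; with several matching regions the one
    with the largest overlap wins, ties broken by genomic order.  Genes
    without a call, without overlap, or with a direction mismatch score
    0 (handled by the caller's fill).
    """
    gene_by_name = {g.gene: g for g in gene_model}
    trees: dict[str, IntervalTree] = {}
    for order, m in enumerate(mcr_regions):
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end, (order, m))

    scores: dict[str, float] = {}
    for call in calls:
        gene = gene_by_name.get(call.gene)
        if gene is None:
            continue
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        best_density: float | None = None
        best_key: tuple[int, int] | None = None
        for iv in tree.overlap(gene.start, gene.end):
            order, mcr = iv.data
            if mcr.direction is not call.direction:
                continue
            overlap = min(mcr.end, gene.end) - max(mcr.start, gene.start)
            key = (overlap, -order)
            if best_key is None or key > best_key:
                best_density, best_key = mcr.density, key
        if best_density is not None:
            # a gene may be called in several patients; keep the max density
            scores[call.gene] = max(scores.get(call.gene, 0.0), best_density)
    return scores


def flag_hotspot_or_double_hit(
    variants: Sequence[AnnotatedVariant],
    calls: Sequence[GeneSCNACall],
    config: FeatureBuildConfig | None = None,
) -> dict[str, int]:
    """Binary flag: hotspot gene (oncogene signal) or double-hit gene.

    A gene is flagged when it carries a mutation with catalogue
    occurrence strictly greater than the hotspot threshold, or when it
    has both a non-synonymous mutation and a homozygous copy-number loss
    (gene-level log2 strictly below the loss threshold).  With
    ``double_hit_same_patient`` both hits must come from one patient.
    """
    config = config or FeatureBuildConfig()
    flags: dict[str, int] = {}
    nonsyn: dict[str, set[str | None]] = {}
    for v in variants:
        if v.occurrence is not None and v.occurrence > config.hotspot_occurrence_min_exclusive:
            flags[v.gene] = 1
        if v.consequence is Consequence.CODING_NONSYNONYMOUS:
            nonsyn.setdefault(v.gene, set()).add(v.patient_id)
    for call in calls:
        if call.log2_ratio >= config.homozygous_loss_log2_max_exclusive:
            continue
        patients = nonsyn.get(call.gene)
        if patients is None:
            continue
        if config.double_hit_same_patient and call.patient_id is not None:
            if call.patient_id not in patients:
                continue
        flags[call.gene] = 1
    return flags


def pathway_membership(gene: str, pathway_sets: PathwayGeneSets) -> np.ndarray:
    """21-vector of 0/1 pathway memberships, in file order."""
    return np.array(
        [1 if gene in s else 0 for s in pathway_sets.sets], dtype=float
    )


def build_feature_matrix(
    variants: Sequence[AnnotatedVariant],
    segments: Sequence[SCNASegment],
    gene_model: Sequence[GeneInterval],
    mcr_regions: Sequence[MCRRegion],
    prior_scores: Mapping[str, float],
    pathway_sets: PathwayGeneSets,
    metapredictor: MetapredictorModel,
    config: FeatureBuildConfig | None = None,
) -> pd.DataFrame:
    """Build the genes x 26 feature matrix for a cohort.

    The gene universe is every gene appearing in the variant table plus
    every gene with a retained SCNA call.  Score features default to the
    configured fill value when a gene has no evidence of that kind.
    Output rows are sorted by gene symbol for determinism.
    """
    config = config or FeatureBuildConfig()
    calls = call_gene_level_scna(segments, gene_model, config)
    return _assemble(
        variants, calls, gene_model, mcr_regions, prior_scores, pathway_sets,
        metapredictor, config,
    )


def build_personalized_features(
    variants: Sequence[AnnotatedVariant],
    segments: Sequence[SCNASegment],
    gene_model: Sequence[GeneInterval],
    mcr_regions: Sequence[MCRRegion],
    prior_scores: Mapping[str, float],
    pathway_sets: PathwayGeneSets,
    metapredictor: MetapredictorModel,
    patient_id: str,
    config: FeatureBuildConfig | None = None,
) -> pd.DataFrame:
    """Feature matrix restricted to a single patient's alterations.

    Identical pipeline to the batch build, run on the subset of variants
    and segments labeled with ``patient_id``; the gene universe is that
    patient's altered genes.
    """
    known = {v.patient_id for v in variants} | {s.patient_id for s in segments}
    known.discard(None)
    if patient_id not in known:
        raise ContractError(
            f"unknown patient '{patient_id}'; known patients: {sorted(known)}"
        )
    my_variants = [v for v in variants if v.patient_id == patient_id]
    my_segments = [s for s in segments if s.patient_id == patient_id]
    config = config or FeatureBuildConfig()
    calls = call_gene_level_scna(my_segments, gene_model, config)
    return _assemble(
        my_variants, calls, gene_model, mcr_regions, prior_scores, pathway_sets,
        metapredictor, config,
    )


def _assemble(
    variants: Sequence[AnnotatedVariant],
    calls: Sequence[GeneSCNACall],
    gene_model: Sequence[GeneInterval],
    mcr_regions: Sequence[MCRRegion],
    prior_scores: Mapping[str, float],
    pathway_sets: PathwayGeneSets,
    metapredictor: MetapredictorModel,
    config: FeatureBuildConfig,
) -> pd.DataFrame:
    universe = sorted({v.gene for v in variants} | {c.gene for c in calls})
    if not universe:
        raise ContractError("gene universe is empty: no variants and no SCNA calls")

    coding = max_coding_impact(variants, metapredictor, config)
    noncoding = max_noncoding_impact(variants, config)
    scna = scna_proxy_score(calls, mcr_regions, gene_model)
    hot = flag_hotspot_or_double_hit(variants, calls, config)

    fill = config.missing_fill
    rows = np.zeros((len(universe), 5 + len(pathway_sets)))
    for i, gene in enumerate(universe):
        rows[i, 0] = coding.get(gene, fill)
        rows[i, 1] = noncoding.get(gene, fill)
        rows[i, 2] = scna.get(gene, fill)
        rows[i, 3] = hot.get(gene, 0)
        rows[i, 4] = prior_scores.get(gene, fill)
        rows[i, 5:] = pathway_membership(gene, pathway_sets)
    return pd.DataFrame(rows, index=pd.Index(universe, name="gene"),
                        columns=feature_names(pathway_sets))
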