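"""Gene-level feature engineering: thresholds, overlaps, matrix assembly."""

from __future__ import annotations

import numpy as np
import pytest
from conftest import make_gene, make_pathways, make_variant

from driverank.feature_builder import (
    BASE_FEATURE_NAMES,
    FeatureBuildConfig,
    build_feature_matrix,
    build_personalized_features,
    call_gene_level_scna,
    flag_hotspot_or_double_hit,
    max_coding_impact,
    max_noncoding_impact,
    pathway_membership,
    scna_proxy_score,
)
from driverank.io_formats import (
    Consequence,
    ContractError,
    MCRDirection,
    MCRRegion,
    SCNASegment,
)

CFG = FeatureBuildConfig()


def seg(start, end, log2, chrom="chr1", patient=None):
    return SCNASegment(chrom=chrom, start=start, end=end, log2_ratio=log2,
                       patient_id=patient)


class TestMaxImpactScores:
    def test_max_over_coding_variants(self, stub_metapredictor):
        variants = [make_variant(score=0.2), make_variant(score=0.9)]
        assert max_coding_impact(variants, stub_metapredictor) == {"G1": 0.9}

    def test_noncoding_only_gene_gets_fill(self, stub_metapredictor):
        variants = [
            make_variant(consequence=Consequence.NONCODING, phred=3.0)
        ]
        assert max_coding_impact(variants, stub_metapredictor) == {}

    def test_unscorable_variant_skipped(self, stub_metapredictor):
        variants = [
            make_variant(scores={"DANN": None}, score=0.9),  # incomplete
            make_variant(score=0.4),
        ]
        assert max_coding_impact(variants, stub_metapredictor) == {"G1": 0.4}

    def test_noncoding_max(self):
        variants = [
            make_variant(consequence=Consequence.NONCODING, phred=3.1),
            make_variant(consequence=Consequence.NONCODING, phred=12.7),
        ]
        assert max_noncoding_impact(variants) == {"G1": 12.7}

    def test_coding_gene_has_no_noncoding_score(self):
        assert max_noncoding_impact([make_variant()]) == {}

    def test_missing_phred_skipped(self):
        variants = [
            make_variant(consequence=Consequence.NONCODING, phred=None),
            make_variant(consequence=Consequence.NONCODING, phred=5.0),
        ]
        assert max_noncoding_impact(variants) == {"G1": 5.0}

    def test_adding_a_variant_never_decreases_the_max(self, stub_metapredictor):
        variants = [make_variant(score=0.6)]
        before = max_coding_impact(variants, stub_metapredictor)["G1"]
        for extra in (0.1, 0.6, 0.95):
            after = max_coding_impact(
                variants + [make_variant(score=extra)], stub_metapredictor
            )["G1"]
            assert after >= before


class TestGeneLevelSCNA:
    GENES = [make_gene("G1", start=10_000)]  # [10000, 20000), length 10000

    def test_quarter_overlap_is_called_inclusive(self):
        # segment covers exactly 25% of the gene
        calls = call_gene_level_scna([seg(10_000, 12_500, 0.6)], self.GENES, CFG)
        assert [c.gene for c in calls] == ["G1"]
        assert calls[0].log2_ratio == 0.6

    def test_below_quarter_overlap_not_called(self):
        calls = call_gene_level_scna([seg(10_000, 12_499, 0.6)], self.GENES, CFG)
        assert calls == []

    def test_amplitude_exactly_at_threshold_kept(self):
        # excluded only when strictly below 0.25
        calls = call_gene_level_scna([seg(10_000, 20_000, 0.25)], self.GENES, CFG)
        assert [c.log2_ratio for c in calls] == [0.25]

    def test_amplitude_below_threshold_dropped(self):
        calls = call_gene_level_scna([seg(10_000, 20_000, 0.1)], self.GENES, CFG)
        assert calls == []

    def test_sex_chromosome_genes_excluded(self):
        genes = [make_gene("GX", chrom="chrX", start=10_000)]
        calls = call_gene_level_scna(
            [seg(10_000, 20_000, 1.2, chrom="chrX")], genes, CFG
        )
        assert calls == []

    def test_max_absolute_log2_wins(self):
        calls = call_gene_level_scna(
            [seg(10_000, 20_000, 0.5), seg(10_000, 20_000, -0.9)], self.GENES, CFG
        )
        assert [c.log2_ratio for c in calls] == [-0.9]

    def test_empty_gene_model_rejected(self):
        with pytest.raises(ContractError):
            call_gene_level_scna([seg(0, 10, 1.0)], [], CFG)


class TestProxyScore:
    GENES = [make_gene("G1", start=10_000)]
    AMP = MCRRegion("chr1", 5_000, 30_000, MCRDirection.AMPLIFICATION, 4.2)
    DEL = MCRRegion("chr1", 5_000, 30_000, MCRDirection.DELETION, 7.7)

    def call(self, log2):
        return call_gene_level_scna(
            [seg(10_000, 20_000, log2)], self.GENES, CFG
        )

    def test_direction_matched_mcr_density_assigned(self):
        assert scna_proxy_score(self.call(0.6), [self.AMP], self.GENES) == {"G1": 4.2}

    def test_direction_mismatch_scores_zero(self):
        assert scna_proxy_score(self.call(-0.6), [self.AMP], self.GENES) == {}

    def test_no_call_scores_zero(self):
        assert scna_proxy_score([], [self.AMP], self.GENES) == {}

    def test_largest_overlap_wins_among_matching(self):
        small = MCRRegion("chr1", 10_000, 12_000, MCRDirection.AMPLIFICATION, 9.9)
        assert scna_proxy_score(
            self.call(0.6), [small, self.AMP], self.GENES
        ) == {"G1": 4.2}


class TestHotspotDoubleHit:
    GENES = [make_gene("G1", start=10_000)]

    def gene_call(self, log2):
        return call_gene_level_scna([seg(10_000, 20_000, log2)], self.GENES, CFG)

    def test_occurrence_six_is_hotspot(self):
        flags = flag_hotspot_or_double_hit([make_variant(occurrence=6)], [], CFG)
        assert flags == {"G1": 1}

    def test_occurrence_five_is_not_hotspot(self):
        flags = flag_hotspot_or_double_hit([make_variant(occurrence=5)], [], CFG)
        assert flags == {}

    def test_nonsynonymous_plus_homozygous_loss_is_double_hit(self):
        flags = flag_hotspot_or_double_hit(
            [make_variant()], self.gene_call(-1.3), CFG
        )
        assert flags == {"G1": 1}

    def test_loss_boundary_minus_one_is_not_double_hit(self):
        flags = flag_hotspot_or_double_hit(
            [make_variant()], self.gene_call(-1.0), CFG
        )
        assert flags == {}

    def test_shallow_loss_is_not_double_hit(self):
        flags = flag_hotspot_or_double_hit(
            [make_variant()], self.gene_call(-0.8), CFG
        )
        assert flags == {}

    def test_synonymous_plus_loss_is_not_double_hit(self):
        flags = flag_hotspot_or_double_hit(
            [make_variant(consequence=Consequence.CODING_OTHER)],
            self.gene_call(-1.3),
            CFG,
        )
        assert flags == {}

    def test_same_patient_switch_requires_co_occurrence(self):
        config = FeatureBuildConfig(double_hit_same_patient=True)
        variants = [make_variant(patient="P1")]
        calls = call_gene_level_scna(
            [seg(10_000, 20_000, -1.5, patient="P2")], self.GENES, config,
            per_patient=True,
        )
        assert flag_hotspot_or_double_hit(variants, calls, config) == {}
        calls_same = call_gene_level_scna(
            [seg(10_000, 20_000, -1.5, patient="P1")], self.GENES, config,
            per_patient=True,
        )
        assert flag_hotspot_or_double_hit(variants, calls_same, config) == {"G1": 1}


class TestPathwayMembership:
    def test_membership_bits_at_given_positions(self):
        sets = make_pathways({3: {"G1"}, 7: {"G1", "G2"}})
        vec = pathway_membership("G1", sets)
        assert vec.shape == (21,)
        assert set(np.flatnonzero(vec)) == {3, 7}

    def test_gene_in_no_set_is_all_zero(self):
        vec = pathway_membership("G9", make_pathways())
        assert not vec.any()


class TestMatrixAssembly:
    def inputs(self, stub):
        genes = [make_gene(f"G{i}", start=10_000 + 60_000 * i) for i in range(10)]
        variants = [
            make_variant(gene=g.gene, score=0.1 * i, patient="P1",
                         pos=g.start + 5)
            for i, g in enumerate(genes)
        ]
        pathways = make_pathways({0: {"G0"}})
        return variants, [], genes, [], {"G0": 2.5}, pathways, stub

    def test_shape_is_genes_by_26(self, stub_metapredictor):
        frame = build_feature_matrix(*self.inputs(stub_metapredictor))
        assert frame.shape == (10, 26)
        assert list(frame.columns[:5]) == list(BASE_FEATURE_NAMES)

    def test_deterministic(self, stub_metapredictor):
        a = build_feature_matrix(*self.inputs(stub_metapredictor))
        b = build_feature_matrix(*self.inputs(stub_metapredictor))
        assert a.equals(b)

    def test_gene_missing_from_priors_fills_zero(self, stub_metapredictor):
        frame = build_feature_matrix(*self.inputs(stub_metapredictor))
        assert frame.loc["G1", "prior_gene_score"] == 0.0
        assert frame.loc["G0", "prior_gene_score"] == 2.5

    def test_empty_universe_rejected(self, stub_metapredictor):
        genes = [make_gene("G1")]
        with pytest.raises(ContractError):
            build_feature_matrix(
                [], [], genes, [], {}, make_pathways(), stub_metapredictor
            )

    def test_personalized_equals_batch_on_single_patient_cohort(
        self, stub_metapredictor
    ):
        variants, _, genes, _, priors, pathways, stub = self.inputs(
            stub_metapredictor
        )
        segments = [seg(10_000, 20_000, 0.8, patient="P1")]
        batch = build_feature_matrix(
            variants, segments, genes, [], priors, pathways, stub
        )
        personal = build_personalized_features(
            variants, segments, genes, [], priors, pathways, stub, "P1"
        )
        assert batch.equals(personal)

    def test_personalized_restricts_to_patient_genes(self, stub_metapredictor):
        genes = [make_gene("G1", start=10_000), make_gene("G2", start=90_000)]
        variants = [
            make_variant(gene="G1", patient="PA", pos=10_100),
            make_variant(gene="G2", patient="PB", pos=90_100),
        ]
        frame = build_personalized_features(
            variants, [], genes, [], {}, make_pathways(), stub_metapredictor, "PB"
        )
        assert list(frame.index) == ["G2"]
        assert frame.loc["G2", "scna_proxy_density"] == 0.0

    def test_unknown_patient_rejected(self, stub_metapredictor):
        variants = [make_variant(patient="PA")]
        with pytest.raises(ContractError, match="PZ"):
            build_personalized_features(
                variants, [], [make_gene("G1")], [], {}, make_pathways(),
                stub_metapredictor, "PZ",
            )
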