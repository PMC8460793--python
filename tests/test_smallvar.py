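"""Small-variant filters, inheritance partitioning, phasing and ranking."""

from __future__ import annotations

import itertools
import random

import pytest

from conftest import make_variant
from varprio.phenotype import GeneScore
from varprio.records import GenomicInterval
from varprio.smallvar import (
    apply_all_filters,
    consequence_filter,
    frequency_filter,
    partition_inheritance,
    pathogenicity_filter,
    pathogenicity_tier,
    phase_block_span,
    phase_relation,
    prefilter,
    rank_small_variants,
)


class TestPrefilter:
    def test_low_gq_dropped(self):
        assert prefilter([make_variant(gq=10)], gq_min=20) == []

    def test_boundary_is_inclusive(self):
        v = make_variant(gq=20, dp=10)
        assert prefilter([v], gq_min=20, dp_min=10, require_pass=True) == [v]

    def test_non_pass_dropped_when_required(self):
        v = make_variant(filter_status="LOWQ")
        assert prefilter([v], require_pass=True) == []
        assert prefilter([v], require_pass=False) == [v]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prefilter([], gq_min=-1)


class TestFrequencyFilter:
    @pytest.mark.parametrize("af, kept", [
        (0.05, True),    # boundary inclusive
        (0.051, False),
        (0.0, True),
        (None, True),    # unobserved = rare
    ])
    def test_af_boundary(self, af, kept):
        v = make_variant(popaf=af)
        assert (frequency_filter([v]) == [v]) is kept


class TestPathogenicityFilter:
    @pytest.mark.parametrize("clinvar, intervar, kept", [
        ("VUS", "LB", False),   # "either" means OR
        ("B", "VUS", False),
        ("P", "VUS", True),
        ("NA", "NA", True),
        ("LP", "LB", False),
    ])
    def test_benign_by_either_classifier(self, clinvar, intervar, kept):
        v = make_variant(clinvar=clinvar, intervar=intervar)
        assert (pathogenicity_filter([v]) == [v]) is kept


class TestConsequenceFilter:
    @pytest.mark.parametrize("csq, kept", [
        ("frameshift", True), ("nonframeshift", True), ("nonsynonymous", True),
        ("stopgain", True), ("stoploss", True), ("splicing", True),
        ("other", False), ("synonymous", False),
    ])
    def test_six_classes_kept(self, csq, kept):
        v = make_variant(consequence=csq)
        assert (consequence_filter([v]) == [v]) is kept


def _random_variants(n=60, seed=7):
    rng = random.Random(seed)
    out = []
    for i in range(n):
        out.append(make_variant(
            pos=100 + i,
            gq=rng.choice([10, 25, 99]),
            dp=rng.choice([5, 15, 40]),
            filter_status=rng.choice(["PASS", "LOWQ"]),
            popaf=rng.choice([None, 0.001, 0.05, 0.2]),
            consequence=rng.choice(["stopgain", "splicing", "other"]),
            clinvar=rng.choice(["NA", "VUS", "B"]),
            intervar=rng.choice(["NA", "LB"]),
        ))
    return out


class TestFilterAlgebra:
    FILTERS = [
        prefilter,
        frequency_filter,
        pathogenicity_filter,
        consequence_filter,
    ]

    def test_each_filter_subset_and_idempotent(self):
        variants = _random_variants()
        for f in self.FILTERS:
            once = f(variants)
            assert set(v.key for v in once) <= set(v.key for v in variants)
            assert f(once) == once

    def test_filters_commute(self):
        variants = _random_variants()
        results = set()
        for order in itertools.permutations(self.FILTERS):
            current = variants
            for f in order:
                current = f(current)
            results.add(tuple(v.key for v in sorted(
                current, key=lambda x: x.key
            )))
        assert len(results) == 1
        ordered = apply_all_filters(variants)
        assert tuple(v.key for v in sorted(ordered, key=lambda x: x.key)) in results


class TestPhase:
    def test_same_block_opposite_haplotypes_is_trans(self):
        v1 = make_variant(pos=10, phase_set="7", haplotype_index=1)
        v2 = make_variant(pos=20, phase_set="7", haplotype_index=2)
        assert phase_relation(v1, v2) == "trans"
        assert phase_relation(v2, v1) == "trans"  # symmetric

    def test_same_block_same_haplotype_is_cis(self):
        v1 = make_variant(pos=10, phase_set="7", haplotype_index=1)
        v2 = make_variant(pos=20, phase_set="7", haplotype_index=1)
        assert phase_relation(v1, v2) == "cis"

    def test_different_or_absent_block_is_unknown(self):
        v1 = make_variant(pos=10, phase_set="7", haplotype_index=1)
        v2 = make_variant(pos=20, phase_set="9", haplotype_index=2)
        v3 = make_variant(pos=30)
        assert phase_relation(v1, v2) == "unknown"
        assert phase_relation(v1, v3) == "unknown"

    def test_cross_chromosome_is_an_error(self):
        v1 = make_variant(chrom="chr1", phase_set="7", haplotype_index=1)
        v2 = make_variant(chrom="chr2", phase_set="7", haplotype_index=2)
        with pytest.raises(ValueError):
            phase_relation(v1, v2)

    def test_phase_block_span(self):
        assert phase_block_span(GenomicInterval("chr21", 100, 100)) == 0
        assert phase_block_span(GenomicInterval("chr1", 1000, 5000)) == 4000


class TestPartitionInheritance:
    def test_de_novo(self):
        v = make_variant(proband=(0, 1), mother=(0, 0), father=(0, 0))
        groups = partition_inheritance([v])
        assert groups["de_novo"] == [v]
        assert groups["dominant_inherited"] == []

    def test_homozygous_recessive(self):
        v = make_variant(proband=(1, 1), mother=(0, 1), father=(0, 1))
        groups = partition_inheritance([v])
        assert groups["homozygous_recessive"] == [v]
        assert groups["de_novo"] == []

    def test_dominant_inherited_from_one_parent(self):
        v = make_variant(proband=(0, 1), mother=(0, 1), father=(0, 0))
        groups = partition_inheritance([v])
        assert groups["dominant_inherited"] == [v]

    def test_compound_het_biparental(self):
        v1 = make_variant(pos=100, proband=(0, 1), mother=(0, 1),
                          father=(0, 0), gene="T")
        v2 = make_variant(pos=200, proband=(0, 1), mother=(0, 0),
                          father=(0, 1), gene="T")
        groups = partition_inheritance([v1, v2])
        assert groups["compound_het"] == [(v1, v2)]

    def test_compound_het_by_phase_alone_in_singleton(self):
        v1 = make_variant(pos=100, proband=(1, 0), mother=None, father=None,
                          phased=True, phase_set="5", haplotype_index=1, gene="T")
        v2 = make_variant(pos=200, proband=(0, 1), mother=None, father=None,
                          phased=True, phase_set="5", haplotype_index=2, gene="T")
        groups = partition_inheritance([v1, v2])
        assert groups["compound_het"] == [(v1, v2)]
        assert groups["de_novo"] == []  # no parents, no de novo call

    def test_cis_pair_not_compound_het(self):
        v1 = make_variant(pos=100, proband=(1, 0), mother=None, father=None,
                          phased=True, phase_set="5", haplotype_index=1, gene="T")
        v2 = make_variant(pos=200, proband=(1, 0), mother=None, father=None,
                          phased=True, phase_set="5", haplotype_index=1, gene="T")
        assert partition_inheritance([v1, v2])["compound_het"] == []

    def test_x_linked_needs_single_x_proband(self):
        v = make_variant(chrom="chrX", proband=(1,), mother=(0, 1), father=(0, 0))
        assert partition_inheritance([v], proband_sex="male")["x_linked"] == [v]
        assert partition_inheritance([v], proband_sex="female")["x_linked"] == []

    def test_never_de_novo_when_a_parent_carries(self):
        rng = random.Random(11)
        gts = [(0, 0), (0, 1), (1, 1)]
        variants = [
            make_variant(pos=i, proband=rng.choice(gts),
                         mother=rng.choice(gts), father=rng.choice(gts))
            for i in range(1, 200)
        ]
        for v in partition_inheritance(variants)["de_novo"]:
            assert not v.member("mother").carries_alt
            assert not v.member("father").carries_alt


class TestRanking:
    SCORES = {
        "HI": GeneScore("HI", 5.0, 1.0),
        "LO": GeneScore("LO", 0.1, 0.02),
        "MID": GeneScore("MID", 2.0, 0.4),
    }

    def test_pathogenicity_dominates_score(self):
        vus_hi = make_variant(pos=10, clinvar="VUS", gene="HI")
        p_lo = make_variant(pos=20, clinvar="P", gene="LO")
        ranked = rank_small_variants({"de_novo": [vus_hi, p_lo]}, self.SCORES)
        assert [c.variant.pos for c in ranked["de_novo"]] == [20, 10]
        assert [c.rank for c in ranked["de_novo"]] == [1, 2]

    def test_score_breaks_ties_within_tier(self):
        a = make_variant(pos=10, clinvar="VUS", gene="MID")
        b = make_variant(pos=20, clinvar="VUS", gene="LO")
        ranked = rank_small_variants({"de_novo": [b, a]}, self.SCORES)
        assert [c.variant.pos for c in ranked["de_novo"]] == [10, 20]

    def test_clinvar_precedence_over_intervar(self):
        v = make_variant(clinvar="VUS", intervar="P")
        assert pathogenicity_tier(v) == 2
        v2 = make_variant(clinvar="NA", intervar="P")
        assert pathogenicity_tier(v2) == 0

    def test_compound_pair_ranked_by_best_member(self):
        p_member = make_variant(pos=10, clinvar="P", gene="LO")
        vus_member = make_variant(pos=20, clinvar="VUS", gene="LO")
        single = make_variant(pos=30, clinvar="LP", gene="HI")
        ranked = rank_small_variants(
            {"compound_het": [(vus_member, p_member)], "de_novo": [single]},
            self.SCORES,
        )
        (pair_call,) = ranked["compound_het"]
        assert pair_call.variant is p_member       # best member leads
        assert pair_call.partner is vus_member
        assert pair_call.rank == 1

    def test_parent_flags_reflect_carrier_status(self):
        v = make_variant(mother=(0, 1), father=(0, 0), gene="HI")
        (call,) = rank_small_variants({"dominant_inherited": [v]}, self.SCORES)[
            "dominant_inherited"
        ]
        assert call.found_in_mother is True
        assert call.found_in_father is False
        assert call.gene_sum_score == 5.0
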