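"""SV overlap primitives, per-type filter modules and screens."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sv
from varprio.io import FeatureMap
from varprio.phenotype import GeneScore, PhenotypeAnnotationMap
from varprio.records import GenomicInterval, ReferenceSvPanel, SyndromeRegion
from varprio.sv import (
    OverlapPolicy,
    cohort_occurrence_screen,
    filter_bionano_indel_dup,
    filter_bionano_inv_transloc,
    filter_tenx,
    flank_intervals,
    quality_outlier_filter,
    reciprocal_overlap,
    syndrome_screen,
)


def oracle_reciprocal(a: GenomicInterval, b: GenomicInterval, fraction: float) -> bool:
    """Brute-force base counting: enumerate the shared integer positions."""
    if a.chrom != b.chrom:
        return False
    shared = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
    la, lb = a.end - a.start, b.end - b.start
    if la == 0 or lb == 0:
        return False
    return shared >= fraction * la and shared >= fraction * lb


class TestReciprocalOverlap:
    def test_identical_intervals_match(self):
        a = GenomicInterval("chr1", 0, 100)
        assert reciprocal_overlap(a, a, 0.5)

    def test_half_overlap_passes_at_half_inclusive(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 50, 150)
        assert reciprocal_overlap(a, b, 0.5)

    def test_asymmetric_small_overlap_fails(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 90, 400)
        assert not reciprocal_overlap(a, b, 0.5)

    def test_zero_length_interval_never_overlaps(self):
        a = GenomicInterval("chr1", 50, 50)
        b = GenomicInterval("chr1", 0, 100)
        assert not reciprocal_overlap(a, b, 0.5)

    def test_different_chromosomes_never_overlap(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr2", 0, 100)
        assert not reciprocal_overlap(a, b, 0.1)

    def test_invalid_fraction_rejected(self):
        a = GenomicInterval("chr1", 0, 100)
        with pytest.raises(ValueError):
            reciprocal_overlap(a, a, 0.0)

    @settings(max_examples=300, derandomize=True)
    @given(
        s1=st.integers(0, 500), l1=st.integers(0, 300),
        s2=st.integers(0, 500), l2=st.integers(0, 300),
        fraction=st.sampled_from([0.1, 0.5, 0.9, 1.0]),
    )
    def test_matches_base_counting_oracle_and_is_symmetric(
        self, s1, l1, s2, l2, fraction
    ):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        got = reciprocal_overlap(a, b, fraction)
        assert got == oracle_reciprocal(a, b, fraction)
        assert got == reciprocal_overlap(b, a, fraction)

    @settings(max_examples=200, derandomize=True)
    @given(
        s1=st.integers(0, 500), l1=st.integers(1, 300),
        s2=st.integers(0, 500), l2=st.integers(1, 300),
    )
    def test_monotone_in_fraction(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        results = [reciprocal_overlap(a, b, f) for f in (0.1, 0.3, 0.5, 0.8, 1.0)]
        # once False, stays False at stricter fractions
        assert results == sorted(results, reverse=True)


class TestFlankIntervals:
    def test_centered_total_width(self):
        sv = make_sv(start=100_000, end=100_000)
        start_iv, _ = flank_intervals(sv, 20_000)
        assert (start_iv.start, start_iv.end) == (90_000, 110_000)

    def test_clamped_at_contig_start(self):
        sv = make_sv(start=4_000, end=4_000)
        start_iv, _ = flank_intervals(sv, 20_000)
        assert (start_iv.start, start_iv.end) == (0, 14_000)

    def test_translocation_spans_two_chromosomes(self):
        sv = make_sv(sv_type="translocation", chrom="chr1", start=49_553_193,
                     chrom2="chr9", end=29_096_673)
        start_iv, end_iv = flank_intervals(sv, 20_000)
        assert start_iv.chrom == "chr1" and end_iv.chrom == "chr9"

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            OverlapPolicy("reciprocal")
        with pytest.raises(ValueError):
            OverlapPolicy("breakpoint_interval", fraction=0.5)
        with pytest.raises(ValueError):
            OverlapPolicy("sideways", fraction=0.5)


class TestBionanoIndelDup:
    def test_low_confidence_eliminated(self):
        calls = [make_sv(id="a", confidence=0.4, source="optical_map")]
        assert filter_bionano_indel_dup(calls, "deletion") == []

    def test_absent_confidence_exempt_from_threshold(self):
        calls = [make_sv(id="a", confidence=None, source="optical_map")]
        assert len(filter_bionano_indel_dup(calls, "deletion")) == 1

    def test_panel_match_removed_type_stratified(self):
        sv = make_sv(id="a", confidence=0.9, source="optical_map")
        same_span_dup = make_sv(id="p1", sv_type="duplication", sample="S1")
        same_span_del = make_sv(id="p2", sv_type="deletion", sample="S2")
        panel_dup = ReferenceSvPanel([same_span_dup])
        panel_del = ReferenceSvPanel([same_span_del])
        assert len(filter_bionano_indel_dup([sv], "deletion", panel=panel_dup)) == 1
        assert filter_bionano_indel_dup([sv], "deletion", panel=panel_del) == []

    def test_parent_flags_annotated_not_filtered(self):
        sv = make_sv(id="a", confidence=0.9)
        in_mother = make_sv(id="m", start=1010, end=2010)
        (call,) = filter_bionano_indel_dup(
            [sv], "deletion", mother=[in_mother], father=[]
        )
        assert call.found_in_mother is True
        assert call.found_in_father is False

    def test_exon_annotation_picks_best_scoring_gene(self):
        sv = make_sv(id="a", confidence=0.9)
        exons = FeatureMap([
            (GenomicInterval("chr1", 1100, 1200), "LOWGENE"),
            (GenomicInterval("chr1", 1500, 1600), "TOPGENE"),
        ])
        ann = PhenotypeAnnotationMap([("HP:1", "TOPGENE")])
        scores = {"TOPGENE": GeneScore("TOPGENE", 2.0, 1.0)}
        (call,) = filter_bionano_indel_dup(
            [sv], "deletion", exons=exons, annotations=ann, gene_scores=scores
        )
        assert call.gene == "TOPGENE"
        assert call.phenotype == "HP:1"


class TestBionanoInvTransloc:
    def test_no_confidence_filtering(self):
        calls = [make_sv(id="i", sv_type="inversion", confidence=0.1)]
        assert len(filter_bionano_inv_transloc(calls, "inversion")) == 1

    def test_panel_match_requires_both_breakpoints_of_same_call(self):
        sv = make_sv(id="t", sv_type="translocation", chrom="chr1",
                     start=1_000_000, chrom2="chr9", end=2_000_000)
        both_ends = make_sv(id="p1", sv_type="translocation", chrom="chr1",
                            start=1_003_000, chrom2="chr9", end=1_998_000,
                            sample="S1")
        one_end = make_sv(id="p2", sv_type="translocation", chrom="chr1",
                          start=1_003_000, chrom2="chr9", end=5_000_000,
                          sample="S2")
        assert filter_bionano_inv_transloc(
            [sv], "translocation", panel=ReferenceSvPanel([both_ends])
        ) == []
        kept = filter_bionano_inv_transloc(
            [sv], "translocation", panel=ReferenceSvPanel([one_end])
        )
        assert len(kept) == 1  # sharing one breakpoint region is not a match

    def test_de_novo_translocation_kept_with_false_flags(self):
        sv = make_sv(id="t", sv_type="translocation", chrom="chr1",
                     start=49_553_193, chrom2="chr9", end=29_096_673)
        (call,) = filter_bionano_inv_transloc(
            [sv], "translocation", panel=ReferenceSvPanel([]),
            mother=[], father=[],
        )
        assert call.found_in_mother is False and call.found_in_father is False

    def test_both_breakpoints_annotated_gene_level(self):
        sv = make_sv(id="t", sv_type="translocation", chrom="chr1",
                     start=1_000_000, chrom2="chr9", end=2_000_000)
        genes = FeatureMap([
            (GenomicInterval("chr1", 990_000, 1_050_000), "AGBL4"),
            (GenomicInterval("chr9", 1_990_000, 2_080_000), "LINGO2"),
        ])
        (call,) = filter_bionano_inv_transloc([sv], "translocation", genes=genes)
        assert (call.gene, call.gene2) == ("AGBL4", "LINGO2")


class TestTenx:
    def test_duplication_matching_father_flagged(self):
        sv = make_sv(id="d", sv_type="duplication", source="linked_read",
                     quality=50.0)
        in_father = make_sv(id="f", sv_type="duplication", start=1005, end=2005)
        (call,) = filter_tenx([sv], "large_svs", "duplication",
                              mother=[], father=[in_father])
        assert call.found_in_father is True
        assert call.found_in_mother is False

    def test_unknown_below_outlier_threshold_dropped(self):
        calls = [
            make_sv(id=f"u{i}", sv_type="unknown", source="linked_read",
                    start=i * 10_000, end=i * 10_000 + 500, quality=q)
            for i, q in enumerate([1.0, 1.0, 1.0, 10.0])
        ]
        kept = filter_tenx(calls, "large_svs", "unknown")
        assert [c.variant.id for c in kept] == ["u3"]

    def test_unmatched_deletion_kept_with_false_flags(self):
        sv = make_sv(id="d", sv_type="deletion", source="linked_read")
        (call,) = filter_tenx([sv], "dels", "deletion",
                              panel=ReferenceSvPanel([]), mother=[], father=[])
        assert call.found_in_mother is False and call.found_in_father is False


class TestQualityOutlier:
    def test_hand_computed_population_sd_case(self):
        # {1,1,1,10}: mean 3.25, population SD ~3.897 -> only 10 passes
        calls = [make_sv(id=f"q{i}", sv_type="unknown", quality=q)
                 for i, q in enumerate([1.0, 1.0, 1.0, 10.0])]
        kept = quality_outlier_filter(calls)
        assert [c.id for c in kept] == ["q3"]

    def test_identical_qualities_pass_nothing(self, caplog):
        calls = [make_sv(id=f"q{i}", sv_type="unknown", quality=5.0)
                 for i in range(3)]
        with caplog.at_level("WARNING"):
            assert quality_outlier_filter(calls) == []
        assert "identical" in caplog.text

    def test_single_call_never_passes(self):
        assert quality_outlier_filter([make_sv(quality=42.0)]) == []

    def test_statistics_are_per_type(self):
        unknowns = [make_sv(id=f"u{i}", sv_type="unknown", quality=q)
                    for i, q in enumerate([1.0, 1.0, 1.0, 10.0])]
        breakends = [
            make_sv(id=f"b{i}", sv_type="breakend", chrom="chr1",
                    start=100, chrom2="chr9", end=200, quality=q)
            for i, q in enumerate([100.0, 100.0, 100.0, 130.0])
        ]
        kept = {c.id for c in quality_outlier_filter(unknowns + breakends)}
        assert kept == {"u3", "b3"}


class TestScreens:
    REGIONS = [
        SyndromeRegion("del_syn", GenomicInterval("chr1", 1000, 5000), "deletion"),
        SyndromeRegion("dup_syn", GenomicInterval("chr1", 1000, 5000), "duplication"),
    ]

    def test_deletion_inside_deletion_region_hits(self):
        sv = make_sv(sv_type="deletion", start=2000, end=3000)
        assert syndrome_screen(sv, self.REGIONS) == ["del_syn"]

    def test_type_mismatch_is_no_hit(self):
        sv = make_sv(sv_type="duplication", start=2000, end=3000)
        assert syndrome_screen(sv, self.REGIONS) == ["dup_syn"]

    def test_no_overlap_is_empty(self):
        sv = make_sv(sv_type="deletion", start=9000, end=9500)
        assert syndrome_screen(sv, self.REGIONS) == []

    def test_screen_restricted_to_cnv_types(self):
        sv = make_sv(sv_type="inversion")
        with pytest.raises(ValueError):
            syndrome_screen(sv, self.REGIONS)

    @pytest.mark.parametrize("n_samples, kept", [(0, True), (2, True), (3, False)])
    def test_cohort_occurrence_boundary(self, n_samples, kept):
        sv = make_sv(id="q", sv_type="deletion")
        cohort = [
            make_sv(id=f"c{i}", start=1010, end=2010, sample=f"S{i}")
            for i in range(n_samples)
        ]
        assert cohort_occurrence_screen(sv, cohort) is kept

    def test_occurrences_count_distinct_samples(self):
        sv = make_sv(id="q", sv_type="deletion")
        cohort = [
            make_sv(id=f"c{i}", start=1010, end=2010, sample="SAME")
            for i in range(5)
        ]
        assert cohort_occurrence_screen(sv, cohort) is True


class TestPanelRemovalOracle:
    def test_matches_all_pairs_base_counting(self):
        """Panel removal equals an O(n*m) brute-force implementation."""
        rng = random.Random(3)
        def rand_calls(n, prefix, sample=None):
            out = []
            for i in range(n):
                start = rng.randrange(0, 5000)
                out.append(make_sv(
                    id=f"{prefix}{i}", start=start,
                    end=start + rng.randrange(1, 400),
                    confidence=0.9, sample=sample,
                ))
            return out

        proband = rand_calls(150, "p")
        panel_calls = rand_calls(120, "n", sample="S")
        kept = {
            c.variant.id
            for c in filter_bionano_indel_dup(
                proband, "deletion", panel=ReferenceSvPanel(panel_calls)
            )
        }
        expected = {
            sv.id for sv in proband
            if not any(
                oracle_reciprocal(sv.interval, p.interval, 0.5)
                for p in panel_calls
            )
        }
        assert kept == expected

    def test_stricter_fraction_never_removes_more(self):
        rng = random.Random(5)
        proband = []
        panel_calls = []
        for i in range(80):
            s = rng.randrange(0, 3000)
            proband.append(make_sv(id=f"p{i}", start=s, end=s + 200,
                                   confidence=0.9))
            t = rng.randrange(0, 3000)
            panel_calls.append(make_sv(id=f"n{i}", start=t, end=t + 200,
                                       sample="S"))
        panel = ReferenceSvPanel(panel_calls)
        kept_by_fraction = [
            len(filter_bionano_indel_dup(proband, "deletion", panel=panel,
                                         fraction=f))
            for f in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert kept_by_fraction == sorted(kept_by_fraction)
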