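"""Structural-variant filtering, panel removal, annotation and screening.

Two matching policies are used, mirroring how SV callers are compared
in practice:

* **reciprocal overlap** — two same-chromosome intervals match at
  fraction *f* when their shared span covers >= *f* of each interval
  (default 0.5).  Used for deletions, insertions and duplications.
* **breakpoint intervals** — windows of a fixed total width are centered
  on each breakpoint (20 kb for optical-map inversions/translocations,
  10 kb for linked-read inversions/unknown/breakends); a panel call
  matches only when *both* of its breakpoints fall in the corresponding
  windows of the same event, so novel fusions sharing one recurrent
  breakpoint region are not spuriously removed.

Matching is type-stratified throughout (deletions only match
deletions, etc.).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .io import FeatureMap
from .phenotype import GeneScore, PhenotypeAnnotationMap
from .records import (
    GenomicInterval,
    PrioritizedCall,
    ReferenceSvPanel,
    StructuralVariant,
    SyndromeRegion,
)

logger = logging.getLogger(__name__)

RECIPROCAL_FRACTION = 0.5
CONFIDENCE_MIN = 0.5
BIONANO_INTERVAL_BP = 20_000
TENX_INTERVAL_BP = 10_000
MAX_COHORT_OCCURRENCES = 2


# ---------------------------------------------------------------------------
# overlap primitives

def reciprocal_overlap(
    a: GenomicInterval, b: GenomicInterval, fraction: float
) -> bool:
    """True when the shared span covers >= fraction of *both* intervals.

    Zero-length intervals never overlap anything; the boundary is
    inclusive (exactly the required fraction passes).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if a.length == 0 or b.length == 0:
        return False
    shared = a.overlap_len(b)
    return shared >= fraction * a.length and shared >= fraction * b.length


def flank_intervals(
    sv: StructuralVariant, flank_total_bp: int
) -> Tuple[GenomicInterval, GenomicInterval]:
    """Windows of total width ``flank_total_bp`` centered on each breakpoint.

    The stated "N kb intervals around the start point and end point" are
    read as total width (+/- N/2), clamped at the contig start.
    """
    if flank_total_bp <= 0:
        raise ValueError("flank_total_bp must be positive")
    half = flank_total_bp // 2
    return (
        GenomicInterval(sv.chrom1, max(0, sv.pos1 - half), sv.pos1 + half),
        GenomicInterval(sv.chrom2, max(0, sv.pos2 - half), sv.pos2 + half),
    )


@dataclass(frozen=True)
class OverlapPolicy:
    """How two SV calls are compared: reciprocal or breakpoint-interval."""

    mode: str
    fraction: Optional[float] = None
    flank_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode == "reciprocal":
            if self.fraction is None or self.flank_bp is not None:
                raise ValueError("reciprocal mode takes fraction only")
        elif self.mode == "breakpoint_interval":
            if self.flank_bp is None or self.fraction is not None:
                raise ValueError("breakpoint_interval mode takes flank_bp only")
        else:
            raise ValueError(f"unknown overlap mode {self.mode!r}")

    def matches(self, a: StructuralVariant, b: StructuralVariant) -> bool:
        """Type-stratified match of two SV calls under this policy."""
        if a.sv_type != b.sv_type:
            return False
        if self.mode == "reciprocal":
            if not (a.is_intrachromosomal and b.is_intrachromosomal):
                return False
            return reciprocal_overlap(a.interval, b.interval, self.fraction)
        start_iv, end_iv = flank_intervals(a, self.flank_bp)
        forward = start_iv.contains_point(b.chrom1, b.pos1) and end_iv.contains_point(
            b.chrom2, b.pos2
        )
        reverse = start_iv.contains_point(b.chrom2, b.pos2) and end_iv.contains_point(
            b.chrom1, b.pos1
        )
        return forward or reverse


RECIPROCAL_POLICY = OverlapPolicy("reciprocal", fraction=RECIPROCAL_FRACTION)


def _matches_any(
    sv: StructuralVariant,
    others: Iterable[StructuralVariant],
    policy: OverlapPolicy,
) -> bool:
    return any(policy.matches(sv, o) for o in others)


# ---------------------------------------------------------------------------
# annotation helpers

def _best_gene(
    genes: Iterable[str],
    gene_scores: Optional[Mapping[str, GeneScore]],
) -> str:
    genes = sorted(genes)
    if not genes:
        return ""
    if gene_scores:
        genes.sort(key=lambda g: (-(gene_scores[g].sum_score
                                    if g in gene_scores else 0.0), g))
    return genes[0]


def _phenotype_of(
    gene: str, annotations: Optional[PhenotypeAnnotationMap]
) -> str:
    if not gene or annotations is None:
        return ""
    return ";".join(sorted(annotations.gene_to_terms.get(gene, ())))


def _annotate_span(
    call: PrioritizedCall,
    features: Optional[FeatureMap],
    annotations: Optional[PhenotypeAnnotationMap],
    gene_scores: Optional[Mapping[str, GeneScore]],
) -> None:
    """Single-interval (exon-level) gene/phenotype annotation."""
    if features is None:
        return
    sv = call.variant
    gene = _best_gene(features.genes_overlapping(sv.interval), gene_scores)
    call.gene = gene
    call.phenotype = _phenotype_of(gene, annotations)


def _annotate_breakpoints(
    call: PrioritizedCall,
    flank_bp: int,
    features: Optional[FeatureMap],
    annotations: Optional[PhenotypeAnnotationMap],
    gene_scores: Optional[Mapping[str, GeneScore]],
) -> None:
    """Two-breakpoint (gene-level) annotation: Gene/Phenotype per end."""
    if features is None:
        return
    sv = call.variant
    start_iv, end_iv = flank_intervals(sv, flank_bp)
    g1 = _best_gene(features.genes_overlapping(start_iv), gene_scores)
    g2 = _best_gene(features.genes_overlapping(end_iv), gene_scores)
    call.gene, call.phenotype = g1, _phenotype_of(g1, annotations)
    call.gene2, call.phenotype2 = g2, _phenotype_of(g2, annotations)


def _typed(
    calls: Optional[Sequence[StructuralVariant]], sv_type: str
) -> Optional[List[StructuralVariant]]:
    """Type-stratified view of a call set; None stays None (no data)."""
    if calls is None:
        return None
    return [c for c in calls if c.sv_type == sv_type]


def _parent_flags(
    sv: StructuralVariant,
    mother: Optional[Sequence[StructuralVariant]],
    father: Optional[Sequence[StructuralVariant]],
    policy: OverlapPolicy,
) -> Tuple[Optional[bool], Optional[bool]]:
    fm = None if mother is None else _matches_any(sv, mother, policy)
    ff = None if father is None else _matches_any(sv, father, policy)
    return fm, ff


# ---------------------------------------------------------------------------
# per-type filter modules

def filter_bionano_indel_dup(
    calls: Iterable[StructuralVariant],
    sv_type: str,
    panel: Optional[ReferenceSvPanel] = None,
    mother: Optional[Sequence[StructuralVariant]] = None,
    father: Optional[Sequence[StructuralVariant]] = None,
    exons: Optional[FeatureMap] = None,
    annotations: Optional[PhenotypeAnnotationMap] = None,
    gene_scores: Optional[Mapping[str, GeneScore]] = None,
    confidence_min: float = CONFIDENCE_MIN,
    fraction: float = RECIPROCAL_FRACTION,
) -> List[PrioritizedCall]:
    """Optical-map deletion/insertion/duplication module.

    Select the type, drop calls below the confidence threshold (calls
    whose caller reports no confidence are exempt), remove calls
    reciprocally matching any panel call of the same type, flag parental
    presence by the same reciprocal criterion, and annotate overlapped
    exons with gene and phenotype.
    """
    policy = OverlapPolicy("reciprocal", fraction=fraction)
    out: List[PrioritizedCall] = []
    selected = [c for c in calls if c.sv_type == sv_type]
    for sv in selected:
        if sv.confidence is not None and sv.confidence < confidence_min:
            continue
        if panel is not None and _matches_any(sv, panel.by_type(sv_type), policy):
            continue
        fm, ff = _parent_flags(
            sv, _typed(mother, sv_type), _typed(father, sv_type), policy
        )
        call = PrioritizedCall(
            variant=sv, found_in_mother=fm, found_in_father=ff,
            group=f"sv_optical_{sv_type}",
        )
        _annotate_span(call, exons, annotations, gene_scores)
        out.append(call)
    logger.info(
        "optical %s module: %d calls in, %d kept", sv_type, len(selected), len(out)
    )
    return out


def filter_bionano_inv_transloc(
    calls: Iterable[StructuralVariant],
    sv_type: str,
    panel: Optional[ReferenceSvPanel] = None,
    mother: Optional[Sequence[StructuralVariant]] = None,
    father: Optional[Sequence[StructuralVariant]] = None,
    genes: Optional[FeatureMap] = None,
    annotations: Optional[PhenotypeAnnotationMap] = None,
    gene_scores: Optional[Mapping[str, GeneScore]] = None,
    flank_bp: int = BIONANO_INTERVAL_BP,
) -> List[PrioritizedCall]:
    """Optical-map inversion/translocation module.

    No confidence filtering.  Panel removal and parental flags use
    breakpoint windows (20 kb total width) with both ends required to
    hit the same panel call; both breakpoints are annotated at gene
    level (Gene/Phenotype and Gene2/Phenotype2).  Survivors are always
    carried into the report.
    """
    policy = OverlapPolicy("breakpoint_interval", flank_bp=flank_bp)
    out: List[PrioritizedCall] = []
    selected = [c for c in calls if c.sv_type == sv_type]
    for sv in selected:
        if panel is not None and _matches_any(sv, panel.by_type(sv_type), policy):
            continue
        fm, ff = _parent_flags(
            sv, _typed(mother, sv_type), _typed(father, sv_type), policy
        )
        call = PrioritizedCall(
            variant=sv, found_in_mother=fm, found_in_father=ff,
            group=f"sv_optical_{sv_type}",
        )
        _annotate_breakpoints(call, flank_bp, genes, annotations, gene_scores)
        out.append(call)
    logger.info(
        "optical %s module: %d calls in, %d kept", sv_type, len(selected), len(out)
    )
    return out


def quality_outlier_filter(
    calls: Sequence[StructuralVariant],
) -> List[StructuralVariant]:
    """Keep calls with quality strictly above mean + 1 SD of their type.

    Mean and population standard deviation are computed over the input
    set per SV type.  When all qualities in a type are identical the SD
    is 0 and, under the strict inequality, nothing passes (warned).
    """
    by_type: Dict[str, List[StructuralVariant]] = {}
    for c in calls:
        by_type.setdefault(c.sv_type, []).append(c)
    kept: List[StructuralVariant] = []
    for sv_type, group in by_type.items():
        quals = [c.quality for c in group if c.quality is not None]
        if not quals:
            continue
        mean = statistics.fmean(quals)
        sd = statistics.pstdev(quals)
        threshold = mean + sd
        passed = [c for c in group
                  if c.quality is not None and c.quality > threshold]
        if sd == 0:
            logger.warning(
                "all %s qualities identical (%g); nothing exceeds mean + SD",
                sv_type, mean,
            )
        kept.extend(passed)
    return kept


def filter_tenx(
    calls: Iterable[StructuralVariant],
    dialect: str,
    sv_type: str,
    panel: Optional[ReferenceSvPanel] = None,
    mother: Optional[Sequence[StructuralVariant]] = None,
    father: Optional[Sequence[StructuralVariant]] = None,
    features: Optional[FeatureMap] = None,
    annotations: Optional[PhenotypeAnnotationMap] = None,
    gene_scores: Optional[Mapping[str, GeneScore]] = None,
    fraction: float = RECIPROCAL_FRACTION,
    flank_bp: int = TENX_INTERVAL_BP,
) -> List[PrioritizedCall]:
    """Linked-read SV modules ("dels" and "large_svs" dialects).

    Deletions and duplications use 50% reciprocal overlap with exon
    annotation; inversions, unknown and breakend types use 10 kb
    breakpoint windows with gene-level annotation of both ends; unknown
    and breakend types additionally pass the quality-outlier filter
    before panel comparison.
    """
    if dialect not in ("dels", "large_svs"):
        raise ValueError(f"unknown dialect {dialect!r}")
    selected = [c for c in calls if c.sv_type == sv_type]
    group_label = f"sv_linked_{sv_type}"
    out: List[PrioritizedCall] = []

    if sv_type in ("deletion", "duplication", "insertion"):
        policy = OverlapPolicy("reciprocal", fraction=fraction)
        for sv in selected:
            if panel is not None and _matches_any(
                sv, panel.by_type(sv_type), policy
            ):
                continue
            fm, ff = _parent_flags(
                sv, _typed(mother, sv_type), _typed(father, sv_type), policy
            )
            call = PrioritizedCall(
                variant=sv, found_in_mother=fm, found_in_father=ff,
                group=group_label,
            )
            _annotate_span(call, features, annotations, gene_scores)
            out.append(call)
    else:
        pool = selected
        if sv_type in ("unknown", "breakend"):
            pool = quality_outlier_filter(selected)
        policy = OverlapPolicy("breakpoint_interval", flank_bp=flank_bp)
        for sv in pool:
            if panel is not None and _matches_any(
                sv, panel.by_type(sv_type), policy
            ):
                continue
            fm, ff = _parent_flags(
                sv, _typed(mother, sv_type), _typed(father, sv_type), policy
            )
            call = PrioritizedCall(
                variant=sv, found_in_mother=fm, found_in_father=ff,
                group=group_label,
            )
            _annotate_breakpoints(call, flank_bp, features, annotations,
                                  gene_scores)
            out.append(call)
    logger.info(
        "linked-read %s module (%s): %d calls in, %d kept",
        sv_type, dialect, len(selected), len(out),
    )
    return out


# ---------------------------------------------------------------------------
# screens

def syndrome_screen(
    sv: StructuralVariant, regions: Sequence[SyndromeRegion]
) -> List[str]:
    """Names of known syndrome regions hit by a deletion/duplication.

    A hit requires type concordance and >= 1 bp of overlap.
    """
    if sv.sv_type not in ("deletion", "duplication"):
        raise ValueError("syndrome screen applies to deletions/duplications")
    return [
        r.name for r in regions
        if r.expected_type == sv.sv_type
        and sv.interval.overlap_len(r.interval) >= 1
    ]


def cohort_occurrence_screen(
    sv: StructuralVariant,
    cohort_calls: Iterable[StructuralVariant],
    policy: OverlapPolicy = RECIPROCAL_POLICY,
    max_occurrences: int = MAX_COHORT_OCCURRENCES,
) -> bool:
    """Keep (True) calls seen in at most ``max_occurrences`` cohort samples.

    Matching is type-stratified under ``policy``; occurrences are
    counted as distinct carrier samples.
    """
    carriers = {
        c.sample for c in cohort_calls
        if c.sample and policy.matches(sv, c)
    }
    return len(carriers) <= max_occurrences
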