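"""Small-variant (SNV/indel) filtering, inheritance partitioning and ranking.

The stream follows the clinical convention: drop likely artifacts
(genotype quality, depth, FILTER), keep rare alleles (population
frequency <= 5%), discard anything called benign/likely benign by either
curated (ClinVar-style) or computed (Intervar-style) classification,
restrict to protein-relevant consequence classes, partition candidates
by inheritance pattern using trio genotypes and haplotype phase, and
rank by reported pathogenicity first, phenotype-matched gene score
second.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .phenotype import GeneScore
from .records import (
    FATHER,
    GenomicInterval,
    MOTHER,
    PROBAND,
    PrioritizedCall,
    SmallVariant,
)

logger = logging.getLogger(__name__)

#: Consequence classes retained by the consequence filter.
KEPT_CONSEQUENCES = frozenset(
    {"frameshift", "nonframeshift", "nonsynonymous", "stopgain", "stoploss",
     "splicing"}
)

BENIGN_CLASSES = frozenset({"B", "LB"})

INHERITANCE_GROUPS = (
    "de_novo", "homozygous_recessive", "compound_het", "x_linked",
    "dominant_inherited",
)

CIS, TRANS, UNKNOWN = "cis", "trans", "unknown"


# ---------------------------------------------------------------------------
# filters — each returns a subset of its input and is idempotent

def prefilter(
    variants: Iterable[SmallVariant],
    gq_min: int = 20,
    dp_min: int = 10,
    require_pass: bool = True,
) -> List[SmallVariant]:
    """Quality prefilter on proband GQ, DP and FILTER (boundary inclusive)."""
    if gq_min < 0 or dp_min < 0:
        raise ValueError("thresholds must be >= 0")
    kept = []
    for v in variants:
        if v.gq is None or v.gq < gq_min:
            continue
        if v.dp is None or v.dp < dp_min:
            continue
        if require_pass and v.filter_status != "PASS":
            continue
        kept.append(v)
    return kept


def frequency_filter(
    variants: Iterable[SmallVariant], af_max: float = 0.05
) -> List[SmallVariant]:
    """Keep rare variants: popAF <= af_max, or popAF absent.

    Absence from the population database cannot mean common, so
    unobserved variants are retained.
    """
    return [v for v in variants if v.popaf is None or v.popaf <= af_max]


def pathogenicity_filter(
    variants: Iterable[SmallVariant],
) -> List[SmallVariant]:
    """Discard variants called benign/likely benign by either classifier."""
    return [
        v for v in variants
        if v.clinvar not in BENIGN_CLASSES and v.intervar not in BENIGN_CLASSES
    ]


def consequence_filter(
    variants: Iterable[SmallVariant],
) -> List[SmallVariant]:
    """Keep exactly the six protein-relevant consequence classes."""
    return [v for v in variants if v.consequence in KEPT_CONSEQUENCES]


def apply_all_filters(
    variants: Iterable[SmallVariant],
    gq_min: int = 20,
    dp_min: int = 10,
    require_pass: bool = True,
    af_max: float = 0.05,
) -> List[SmallVariant]:
    """Run the four small-variant filters; order-independent result."""
    out = prefilter(variants, gq_min, dp_min, require_pass)
    logger.info("prefilter kept %d variants", len(out))
    out = frequency_filter(out, af_max)
    logger.info("frequency filter kept %d variants", len(out))
    out = pathogenicity_filter(out)
    logger.info("benign-exclusion filter kept %d variants", len(out))
    out = consequence_filter(out)
    logger.info("consequence filter kept %d variants", len(out))
    return out


# ---------------------------------------------------------------------------
# phase

def phase_relation(v1: SmallVariant, v2: SmallVariant) -> str:
    """cis/trans/unknown relation of two proband variants.

    Defined through the phase set: same block and same haplotype index
    -> cis; same block, different index -> trans; otherwise unknown.
    """
    if v1.chrom != v2.chrom:
        raise ValueError("phase relation requires the same chromosome")
    if (
        v1.phase_set is None
        or v2.phase_set is None
        or v1.phase_set != v2.phase_set
        or v1.haplotype_index is None
        or v2.haplotype_index is None
    ):
        return UNKNOWN
    return CIS if v1.haplotype_index == v2.haplotype_index else TRANS


def phase_block_span(block: GenomicInterval) -> int:
    """Span of a phase block in bp (end - start)."""
    return block.length


# ---------------------------------------------------------------------------
# inheritance partitioning

def _is_x(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() == "X"


def _parents_genotyped(v: SmallVariant) -> bool:
    m, f = v.member(MOTHER), v.member(FATHER)
    return (
        m is not None and f is not None
        and not m.is_missing and not f.is_missing
    )


CandidateSets = Dict[str, list]


def partition_inheritance(
    variants: Sequence[SmallVariant],
    proband_sex: str = "unknown",
) -> CandidateSets:
    """Partition filtered variants into candidate inheritance groups.

    Trio logic: de novo (proband carries the allele, both parents
    homozygous reference), homozygous recessive (proband hom-alt, both
    parents het), compound het (>= 2 het variants in one gene, one from
    each parent or in trans by phase), X-linked (hemizygous pattern on a
    single-X proband), dominant inherited (het shared with exactly one
    parent).  A variant may appear in several groups.  In singleton mode
    (parents ungenotyped) only phase-based compound hets and hemizygous
    X-linked candidates can be produced.
    """
    groups: CandidateSets = {g: [] for g in INHERITANCE_GROUPS}
    carriers = [v for v in variants if v.proband.carries_alt]
    for v in carriers:
        pro = v.proband
        trio = _parents_genotyped(v)
        mother_alt = trio and v.member(MOTHER).carries_alt
        father_alt = trio and v.member(FATHER).carries_alt
        if trio:
            if v.member(MOTHER).is_hom_ref and v.member(FATHER).is_hom_ref:
                groups["de_novo"].append(v)
            if pro.is_hom_alt and v.member(MOTHER).is_het and v.member(FATHER).is_het:
                groups["homozygous_recessive"].append(v)
            if pro.is_het and (mother_alt != father_alt):
                groups["dominant_inherited"].append(v)
        if _is_x(v.chrom) and proband_sex == "male":
            father_ok = (not trio) or v.member(FATHER).is_hom_ref
            if (pro.is_hemizygous or pro.carries_alt) and father_ok:
                groups["x_linked"].append(v)

    # compound hets: pairs of proband-het variants within one gene
    by_gene: Dict[str, List[SmallVariant]] = {}
    for v in carriers:
        if v.gene and v.proband.is_het:
            by_gene.setdefault(v.gene, []).append(v)
    for gene, vs in by_gene.items():
        for v1, v2 in combinations(vs, 2):
            if v1.chrom != v2.chrom:
                continue
            trio = _parents_genotyped(v1) and _parents_genotyped(v2)
            biparental = False
            if trio:
                m1, f1 = v1.member(MOTHER).carries_alt, v1.member(FATHER).carries_alt
                m2, f2 = v2.member(MOTHER).carries_alt, v2.member(FATHER).carries_alt
                biparental = (m1 and not f1 and f2 and not m2) or (
                    f1 and not m1 and m2 and not f2
                )
            in_trans = phase_relation(v1, v2) == TRANS
            if biparental or in_trans:
                groups["compound_het"].append((v1, v2))
    return groups


# ---------------------------------------------------------------------------
# ranking

_TIER = {"P": 0, "LP": 1}


def pathogenicity_tier(v: SmallVariant) -> int:
    """0 for P, 1 for LP, 2 for VUS/NA; curated class takes precedence."""
    for cls in (v.clinvar, v.intervar):
        if cls in ("P", "LP", "VUS", "LB", "B"):
            return _TIER.get(cls, 2)
    return 2


def _chrom_sort_key(chrom: str) -> Tuple[int, str]:
    core = chrom.removeprefix("chr")
    return (0, core.zfill(9)) if core.isdigit() else (1, core)


def _score_of(gene: Optional[str], gene_scores: Mapping[str, GeneScore]) -> GeneScore:
    if gene and gene in gene_scores:
        return gene_scores[gene]
    return GeneScore(gene or "", 0.0, 0.0)


def _sort_key(v: SmallVariant, gene_scores: Mapping[str, GeneScore]) -> tuple:
    return (
        pathogenicity_tier(v),
        -_score_of(v.gene, gene_scores).sum_score,
        _chrom_sort_key(v.chrom),
        v.pos,
    )


def rank_small_variants(
    candidates: CandidateSets,
    gene_scores: Mapping[str, GeneScore],
) -> Dict[str, List[PrioritizedCall]]:
    """Order candidates within each inheritance group.

    Sort key: pathogenicity tier (P > LP > VUS/NA), then gene sum score
    descending, then genomic position.  Compound-het pairs are ranked by
    their best member and reported as one call with the partner
    attached.  Ranks are contiguous from 1 within each group.
    """
    ranked: Dict[str, List[PrioritizedCall]] = {}
    for group, entries in candidates.items():
        calls: List[PrioritizedCall] = []
        keyed = []
        for entry in entries:
            if isinstance(entry, tuple):
                k1, k2 = (_sort_key(v, gene_scores) for v in entry)
                primary, partner = (entry if k1 <= k2 else entry[::-1])
                keyed.append((min(k1, k2), primary, partner))
            else:
                keyed.append((_sort_key(entry, gene_scores), entry, None))
        keyed.sort(key=lambda t: t[0])
        for rank, (_, primary, partner) in enumerate(keyed, start=1):
            score = _score_of(primary.gene, gene_scores)
            trio = _parents_genotyped(primary)
            calls.append(
                PrioritizedCall(
                    variant=primary,
                    partner=partner,
                    found_in_mother=(
                        primary.member(MOTHER).carries_alt if trio else None
                    ),
                    found_in_father=(
                        primary.member(FATHER).carries_alt if trio else None
                    ),
                    gene=primary.gene or "",
                    group=group,
                    rank=rank,
                    gene_sum_score=score.sum_score,
                    normalized_score=score.normalized_score,
                )
            )
        ranked[group] = calls
    return ranked
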