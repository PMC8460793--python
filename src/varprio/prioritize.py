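"""Merging of candidate streams, score attachment and final ranking.

Small-variant and SV candidates stay in separate inheritance/SV groups;
within a group, small variants are ordered by pathogenicity tier then
phenotype-matched gene score, and SVs by gene score then position.
Normalized scores (shared max-normalization from the gene ranking) act
as the per-call confidence score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from . import io as vio
from .phenotype import (
    GeneScore,
    PatientPhenome,
    PhenotypeAnnotationMap,
    assemble_phenome,
    load_ontology,
    rank_genes,
)
from .records import PrioritizedCall, SmallVariant, StructuralVariant
from .smallvar import (
    apply_all_filters,
    partition_inheritance,
    rank_small_variants,
    _chrom_sort_key,
)
from .sv import (
    BIONANO_INTERVAL_BP,
    CONFIDENCE_MIN,
    MAX_COHORT_OCCURRENCES,
    OverlapPolicy,
    RECIPROCAL_FRACTION,
    TENX_INTERVAL_BP,
    cohort_occurrence_screen,
    filter_bionano_indel_dup,
    filter_bionano_inv_transloc,
    filter_tenx,
    syndrome_screen,
)

logger = logging.getLogger(__name__)


def attach_gene_scores(
    calls: Iterable[PrioritizedCall],
    gene_scores: Mapping[str, GeneScore],
) -> List[PrioritizedCall]:
    """Attach each call's best overlapped gene score.

    Calls with no gene overlap score 0 but are not dropped; inversions,
    translocations and breakends are reported regardless of score.
    """
    out = []
    for call in calls:
        best = GeneScore("", 0.0, 0.0)
        for g in call.genes:
            s = gene_scores.get(g)
            if s is not None and s.sum_score > best.sum_score:
                best = s
        call.gene_sum_score = best.sum_score
        call.normalized_score = best.normalized_score
        out.append(call)
    return out


@dataclass
class CaseResult:
    """Per-group ordered candidate lists plus summary counts."""

    groups: Dict[str, List[PrioritizedCall]] = field(default_factory=dict)

    @property
    def counts(self) -> Dict[str, int]:
        return {g: len(calls) for g, calls in self.groups.items()}

    @property
    def all_calls(self) -> List[PrioritizedCall]:
        return [c for calls in self.groups.values() for c in calls]

    def top(self, group: str) -> Optional[PrioritizedCall]:
        calls = self.groups.get(group) or []
        return calls[0] if calls else None

    def summary(self) -> Dict[str, object]:
        return {"groups": self.counts, "total": sum(self.counts.values())}


def _sv_sort_key(call: PrioritizedCall) -> tuple:
    v = call.variant
    return (
        -call.gene_sum_score,
        _chrom_sort_key(v.chrom1),
        v.pos1,
        v.id,
    )


def finalize_case(
    small_groups: Optional[Mapping[str, Sequence[PrioritizedCall]]] = None,
    sv_calls: Optional[Sequence[PrioritizedCall]] = None,
) -> CaseResult:
    """Assemble the final per-group ranking; deterministic for fixed input."""
    result = CaseResult()
    for group, calls in (small_groups or {}).items():
        ordered = list(calls)  # already ordered by rank_small_variants
        for rank, call in enumerate(ordered, start=1):
            call.rank = rank
        result.groups[group] = ordered
    by_group: Dict[str, List[PrioritizedCall]] = {}
    for call in sv_calls or []:
        by_group.setdefault(call.group or "sv_other", []).append(call)
    for group in sorted(by_group):
        ordered = sorted(by_group[group], key=_sv_sort_key)
        for rank, call in enumerate(ordered, start=1):
            call.rank = rank
        result.groups[group] = ordered
    return result


# ---------------------------------------------------------------------------
# case drivers

def build_gene_scores(
    ontology_path, annotations_path, phenome_path
) -> tuple:
    """Load ontology + annotations, assemble the phenome, rank genes.

    Returns (phenome, annotations, ranked GeneScore list, dict by gene).
    """
    ontology = load_ontology(ontology_path)
    annotations = PhenotypeAnnotationMap.from_tsv(annotations_path)
    curated, nlp = vio.load_phenome_json(phenome_path)
    phenome = assemble_phenome(curated, nlp, ontology)
    ranked = rank_genes(phenome, annotations)
    return phenome, annotations, ranked, {s.gene: s for s in ranked}


def run_small_variant_case(
    variants: Sequence[SmallVariant],
    gene_scores: Mapping[str, GeneScore],
    gq_min: int = 20,
    dp_min: int = 10,
    require_pass: bool = True,
    af_max: float = 0.05,
    proband_sex: str = "unknown",
) -> Dict[str, List[PrioritizedCall]]:
    """Filter, partition and rank the small-variant stream."""
    kept = apply_all_filters(variants, gq_min, dp_min, require_pass, af_max)
    groups = partition_inheritance(kept, proband_sex=proband_sex)
    return rank_small_variants(groups, gene_scores)


def run_sv_case(
    proband_smap: Sequence[StructuralVariant] = (),
    mother_smap: Optional[Sequence[StructuralVariant]] = None,
    father_smap: Optional[Sequence[StructuralVariant]] = None,
    tenx_large: Sequence[StructuralVariant] = (),
    tenx_dels: Sequence[StructuralVariant] = (),
    panel=None,
    cohort=None,
    syndromes: Sequence = (),
    exons=None,
    genes=None,
    annotations: Optional[PhenotypeAnnotationMap] = None,
    gene_scores: Optional[Mapping[str, GeneScore]] = None,
    confidence_min: float = CONFIDENCE_MIN,
    fraction: float = RECIPROCAL_FRACTION,
    bionano_interval_bp: int = BIONANO_INTERVAL_BP,
    tenx_interval_bp: int = TENX_INTERVAL_BP,
    max_cohort_occurrences: int = MAX_COHORT_OCCURRENCES,
) -> List[PrioritizedCall]:
    """Run every SV module and the cohort/syndrome screens.

    Optical-map deletions/insertions/duplications and linked-read
    deletions/duplications go through confidence (optical only) and
    reciprocal-overlap filtering; inversions, translocations, unknown
    and breakend calls through breakpoint-interval filtering (with the
    quality-outlier rule for linked-read unknown/breakend).
    """
    gene_scores = gene_scores or {}
    calls: List[PrioritizedCall] = []
    for sv_type in ("deletion", "insertion", "duplication"):
        calls.extend(
            filter_bionano_indel_dup(
                proband_smap, sv_type, panel, mother_smap, father_smap,
                exons, annotations, gene_scores,
                confidence_min=confidence_min, fraction=fraction,
            )
        )
    for sv_type in ("inversion", "translocation"):
        calls.extend(
            filter_bionano_inv_transloc(
                proband_smap, sv_type, panel, mother_smap, father_smap,
                genes, annotations, gene_scores, flank_bp=bionano_interval_bp,
            )
        )
    # parents' optical-map calls double as the parental comparison set for
    # the linked-read stream (matching is type- and interval-based, so the
    # source platform of the comparison call does not matter)
    calls.extend(
        filter_tenx(
            tenx_dels, "dels", "deletion", panel, mother_smap, father_smap,
            exons, annotations, gene_scores, fraction=fraction,
        )
    )
    for sv_type in ("deletion", "duplication"):
        calls.extend(
            filter_tenx(
                tenx_large, "large_svs", sv_type, panel, mother_smap,
                father_smap, exons, annotations, gene_scores,
                fraction=fraction,
            )
        )
    for sv_type in ("inversion", "unknown", "breakend"):
        calls.extend(
            filter_tenx(
                tenx_large, "large_svs", sv_type, panel, mother_smap,
                father_smap, genes, annotations, gene_scores,
                flank_bp=tenx_interval_bp,
            )
        )

    if cohort is not None:
        policy = OverlapPolicy("reciprocal", fraction=fraction)
        before = len(calls)
        calls = [
            c for c in calls
            if not c.variant.is_intrachromosomal
            or c.variant.sv_type in ("translocation", "breakend", "inversion")
            or cohort_occurrence_screen(
                c.variant, cohort, policy, max_cohort_occurrences
            )
        ]
        logger.info("cohort screen kept %d of %d SV calls", len(calls), before)

    if syndromes:
        for c in calls:
            if c.variant.sv_type in ("deletion", "duplication"):
                c.syndrome_hits = syndrome_screen(c.variant, syndromes)

    return attach_gene_scores(calls, gene_scores)


def write_summary_json(result: CaseResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
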