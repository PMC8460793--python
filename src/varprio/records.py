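"""Core domain records shared across the pipeline.

Coordinate convention: every interval held in memory is 0-based,
half-open ``[start, end)``.  External formats (VCF, SMAP: 1-based) are
converted on read and back on write.  Structural-variant breakpoints are
stored as 0-based *points*, so the span of an intrachromosomal event is
simply ``pos2 - pos1`` — the convention under which the breakpoint pairs
reported for clinical deletions/duplications reproduce their published
sizes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

SV_TYPES = frozenset(
    {"deletion", "insertion", "duplication", "inversion", "translocation",
     "breakend", "unknown"}
)

#: Clinical significance vocabulary used by both ClinVar- and
#: Intervar-style annotation fields.
PATHOGENICITY_CLASSES = ("P", "LP", "VUS", "LB", "B", "NA")

PROBAND, MOTHER, FATHER = "proband", "mother", "father"
TRIO_ROLES = (PROBAND, MOTHER, FATHER)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different contigs)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class MemberGenotype:
    """One family member's genotype at a (decomposed, biallelic) site.

    ``alleles`` holds 0 (ref), 1 (alt) or None (missing) per haplotype.
    """

    alleles: tuple
    phased: bool = False
    gq: Optional[int] = None
    dp: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return len(self.alleles) == 0 or all(a is None for a in self.alleles)

    @property
    def carries_alt(self) -> bool:
        return any(a == 1 for a in self.alleles)

    @property
    def is_het(self) -> bool:
        called = [a for a in self.alleles if a is not None]
        return len(called) == 2 and sorted(called) == [0, 1]

    @property
    def is_hom_alt(self) -> bool:
        called = [a for a in self.alleles if a is not None]
        return len(called) >= 1 and all(a == 1 for a in called) and 1 in called

    @property
    def is_hom_ref(self) -> bool:
        called = [a for a in self.alleles if a is not None]
        return len(called) >= 1 and all(a == 0 for a in called)

    @property
    def is_hemizygous(self) -> bool:
        called = [a for a in self.alleles if a is not None]
        return len(called) == 1


@dataclass
class SmallVariant:
    """An annotated, phase-aware small-variant record (one ALT allele).

    ``pos`` is 1-based as in VCF.  ``haplotype_index`` (1 or 2) gives the
    haplotype carrying the ALT allele within ``phase_set``, and is only
    present when the proband genotype is phased and heterozygous.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Mapping[str, MemberGenotype]
    filter_status: str = "PASS"
    popaf: Optional[float] = None
    consequence: str = "other"
    clinvar: str = "NA"
    intervar: str = "NA"
    phase_set: Optional[str] = None
    haplotype_index: Optional[int] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref/alt alleles must be non-empty")
        if self.popaf is not None and not (0.0 <= self.popaf <= 1.0):
            raise ValueError(f"popAF {self.popaf} outside [0,1]")
        if self.haplotype_index is not None and self.phase_set is None:
            raise ValueError("haplotype_index requires a phase_set")

    def member(self, role: str) -> Optional[MemberGenotype]:
        return self.genotypes.get(role)

    @property
    def proband(self) -> MemberGenotype:
        return self.genotypes[PROBAND]

    @property
    def gq(self) -> Optional[int]:
        return self.proband.gq

    @property
    def dp(self) -> Optional[int]:
        return self.proband.dp

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class StructuralVariant:
    """A unified SV record from optical-mapping or linked-read sources.

    Breakpoints are 0-based points; for intrachromosomal events
    ``pos1 <= pos2`` and ``length == pos2 - pos1``.  ``confidence`` is the
    optical-map call confidence in [0, 1] (None when the caller reports
    none); ``quality`` is the linked-read Phred-scaled QUAL.
    """

    id: str
    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    confidence: Optional[float] = None
    quality: Optional[float] = None
    source: str = "optical_map"
    zygosity: str = "unknown"
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            raise ValueError(
                f"{self.id}: pos1 > pos2 on intrachromosomal call"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"{self.id}: confidence outside [0,1]")

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def length(self) -> Optional[int]:
        if self.sv_type in ("translocation", "breakend") or not self.is_intrachromosomal:
            return None
        return self.pos2 - self.pos1

    @property
    def interval(self) -> GenomicInterval:
        if not self.is_intrachromosomal:
            raise ValueError(f"{self.id}: interval undefined across contigs")
        return GenomicInterval(self.chrom1, self.pos1, self.pos2)


class ReferenceSvPanel:
    """Control SV call set (population cohort plus unrelated parents).

    Calls carry sample identifiers so occurrence screening can count
    distinct carriers.
    """

    def __init__(self, calls: Iterable[StructuralVariant]):
        self.calls = list(calls)
        self._by_type: dict = {}
        for c in self.calls:
            self._by_type.setdefault(c.sv_type, []).append(c)

    def by_type(self, sv_type: str) -> Sequence[StructuralVariant]:
        return self._by_type.get(sv_type, [])

    @property
    def samples(self) -> set:
        return {c.sample for c in self.calls if c.sample}

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[StructuralVariant]:
        return iter(self.calls)


@dataclass(frozen=True)
class SyndromeRegion:
    """A genomic region of a known microdeletion/microduplication syndrome."""

    name: str
    interval: GenomicInterval
    expected_type: str

    def __post_init__(self) -> None:
        if self.expected_type not in ("deletion", "duplication"):
            raise ValueError(
                f"{self.name}: expected_type must be deletion or duplication"
            )


@dataclass
class PrioritizedCall:
    """A variant decorated with trio, gene/phenotype and ranking columns.

    ``gene2``/``phenotype2`` are populated only for two-breakpoint
    annotations (inversions, translocations, breakends).  ``partner``
    holds the second member of a compound-heterozygous pair; the pair is
    reported as a single row ranked by its best member.
    """

    variant: Union[SmallVariant, StructuralVariant]
    found_in_mother: Optional[bool] = None
    found_in_father: Optional[bool] = None
    gene: str = ""
    phenotype: str = ""
    gene2: str = ""
    phenotype2: str = ""
    syndrome_hits: list = field(default_factory=list)
    group: Optional[str] = None
    rank: Optional[int] = None
    gene_sum_score: float = 0.0
    normalized_score: float = 0.0
    partner: Optional[SmallVariant] = None

    @property
    def genes(self) -> set:
        return {g for g in (self.gene, self.gene2) if g}
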