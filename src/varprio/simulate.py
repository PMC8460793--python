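"""Deterministic synthetic fixtures for the whole pipeline.

The generator emulates the pipeline's study conditions on a toy genome
(three 10-Mb contigs with a fabricated gene/exon map): a small
phenotype ontology whose term-to-gene counts make the inverse-gene-count
weights vary, a Mendelian-consistent trio of small variants with the
population-frequency mixture the frequency filter expects (90% common
sites at AF 5-50%, 10% rare), optical-map and linked-read SV call sets
with panel/parent sharing, and five planted diagnostic events:

* a de novo pathogenic SNV in a phenome-matched gene,
* a compound-heterozygous pair in trans, 50-200 kb apart in one phase
  block of one gene, one allele from each parent,
* a ~32 kb de novo duplication overlapping exons of a phenome-matched
  gene (called by both platforms),
* a biallelic deletion (proband homozygous; each parent a heterozygous
  carrier),
* a de novo translocation between two contigs (optical-map call plus a
  linked-read breakend pair).

Every emitted file is a deterministic function of the seed and
round-trips through the :mod:`varprio.io` readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as vio
from .phenotype import Ontology, PhenotypeAnnotationMap
from .records import (
    FATHER,
    GenomicInterval,
    MemberGenotype,
    MOTHER,
    PROBAND,
    SmallVariant,
    StructuralVariant,
)

CONTIGS = {"chr1": 10_000_000, "chr2": 10_000_000, "chrX": 10_000_000}

# planted loci (0-based); background placement avoids the exclusion zones
PLANTED_GENES = {
    "DNGENE": ("chr1", 9_000_000, 9_020_000),
    "CHGENE": ("chr1", 8_400_000, 8_650_000),
    "TRGENE1": ("chr1", 4_000_000, 4_100_000),
    "DUPGENE": ("chr2", 8_000_000, 8_060_000),
    "DELGENE": ("chr2", 8_600_000, 8_650_000),
    "TRGENE2": ("chr2", 6_000_000, 6_100_000),
}
_EXCLUSION = {
    "chr1": [(3_900_000, 4_200_000), (8_300_000, 9_100_000)],
    "chr2": [(5_900_000, 6_200_000), (7_900_000, 8_700_000)],
    "chrX": [],
}

DUP_BREAKPOINTS = ("chr2", 8_005_000, 8_037_037)      # 32,037 bp
DEL_BREAKPOINTS = ("chr2", 8_605_000, 8_641_077)      # 36,077 bp
TRANSLOC_BREAKPOINTS = ("chr1", 4_050_000, "chr2", 6_050_000)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic case; the seed fixes everything."""

    seed: int = 1
    n_background_small_variants: int = 300
    n_background_svs: int = 30
    n_background_de_novo_snvs: int = 2
    panel_size: int = 20
    cohort_size: int = 10
    common_af_fraction: float = 0.9
    parent_share_rate: float = 0.4
    panel_share_rate: float = 0.6
    proband_sex: str = "unknown"


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# gene / exon layout (fixed, seed-independent)

def gene_spans() -> List[Tuple[GenomicInterval, str]]:
    spans = []
    for i in range(60):
        chrom = "chr1" if i < 30 else "chr2"
        start = 200_000 + (i % 30) * 250_000
        spans.append((GenomicInterval(chrom, start, start + 20_000), f"G{i:03d}"))
    for gene, (chrom, start, end) in PLANTED_GENES.items():
        spans.append((GenomicInterval(chrom, start, end), gene))
    return spans


def exon_spans() -> List[Tuple[GenomicInterval, str]]:
    exons = []
    for iv, gene in gene_spans():
        step = max((iv.length - 200) // 5, 10_000) if iv.length > 50_000 else 4_000
        pos = iv.start
        while pos + 200 <= iv.end:
            exons.append((GenomicInterval(iv.chrom, pos, pos + 200), gene))
            pos += step
    return exons


def _write_features(features, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tstart\tend\tgene\n")
        for iv, gene in features:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\n")


# ---------------------------------------------------------------------------
# ontology and annotations

def make_toy_ontology_and_annotations(
    config: SimulationConfig,
) -> Tuple[Ontology, PhenotypeAnnotationMap, List[str], List[str]]:
    """Build the toy phenotype ontology, annotation map and term lists.

    The DAG has depth 3 (root, 5 branch terms, 15 mid-level terms, 14
    leaves) so one-degree expansion is distinguishable from full
    ancestor closure.  Twelve leaves are annotated to exactly one
    planted gene each (weight 1.0); mid-level terms carry 5-20
    background genes so weights span the (0, 1] range.
    """
    rng = _rng(config, 1)
    from .phenotype import HpoTerm

    terms = [HpoTerm("HP:0000001", "phenotypic abnormality")]
    level1 = [f"HP:{10 + i:07d}" for i in range(5)]
    terms += [HpoTerm(t, f"branch {i}", {"HP:0000001"})
              for i, t in enumerate(level1)]
    level2 = [f"HP:{100 + i:07d}" for i in range(15)]
    terms += [HpoTerm(t, f"mid {i}", {level1[i % 5]})
              for i, t in enumerate(level2)]
    level3 = [f"HP:{200 + i:07d}" for i in range(14)]
    terms += [HpoTerm(t, f"leaf {i}", {level2[i % 15]})
              for i, t in enumerate(level3)]
    ontology = Ontology(terms)

    background_genes = [f"G{i:03d}" for i in range(60)]
    pairs: List[Tuple[str, str]] = []
    planted = list(PLANTED_GENES)
    for j, gene in enumerate(planted):              # two leaves per gene
        pairs.append((level3[2 * j], gene))
        pairs.append((level3[2 * j + 1], gene))
    for term in level2 + level3[12:]:
        k = int(rng.integers(5, 21))
        for g in rng.choice(background_genes, size=k, replace=False):
            pairs.append((term, str(g)))
    annotations = PhenotypeAnnotationMap(pairs)

    curated = level3[:12]
    nlp = [str(t) for t in rng.choice(level2, size=2, replace=False)]
    return ontology, annotations, curated, nlp


# ---------------------------------------------------------------------------
# small variants

_BASES = np.array(list("ACGT"))


def _hwe_genotype(rng, af: float) -> Tuple[int, int]:
    return tuple(int(rng.random() < af) for _ in range(2))


def _inherit(rng, mother: Tuple[int, int], father: Tuple[int, int]) -> Tuple[int, int]:
    return (mother[int(rng.integers(2))], father[int(rng.integers(2))])


def simulate_trio_small_variants(
    config: SimulationConfig,
) -> Tuple[List[SmallVariant], Dict[str, dict]]:
    """Background trio sites plus the planted SNV/indel events.

    Returns the variant list and the planted-truth descriptors.
    """
    rng = _rng(config, 2)
    genes = vio.FeatureMap(gene_spans())
    used: set = set()
    variants: List[SmallVariant] = []

    def draw_pos(chrom: str) -> int:
        for _ in range(200):
            pos = int(rng.integers(100_000, CONTIGS[chrom] - 100_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return pos
        raise RuntimeError("could not place variant without collision")

    def make_member(alleles, phased=False, gq=None, dp=None):
        return MemberGenotype(tuple(alleles), phased=phased, gq=gq, dp=dp)

    n = config.n_background_small_variants
    for _ in range(n):
        r = rng.random()
        chrom = "chrX" if r < 0.05 else ("chr1" if r < 0.55 else "chr2")
        pos0 = draw_pos(chrom)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        if rng.random() < config.common_af_fraction:
            af: Optional[float] = float(rng.uniform(0.05, 0.5))
        else:
            af = float(rng.uniform(1e-5, 0.04))
            if rng.random() < 0.1:
                af = None
        af_draw = 0.2 if af is None else af
        mom = _hwe_genotype(rng, af_draw)
        dad = _hwe_genotype(rng, af_draw)
        kid = _inherit(rng, mom, dad)
        gq = int(rng.integers(30, 100)) if rng.random() > 0.05 else int(rng.integers(5, 20))
        dp = max(1, int(rng.poisson(35))) if rng.random() > 0.03 else int(rng.integers(2, 10))
        filt = "PASS" if rng.random() > 0.05 else "LOWQ"
        csq = (
            "other" if rng.random() < 0.6
            else str(rng.choice(["frameshift", "nonframeshift", "nonsynonymous",
                                 "stopgain", "stoploss", "splicing"]))
        )
        clv = str(rng.choice(["NA", "VUS", "LB", "B"], p=[0.8, 0.1, 0.05, 0.05]))
        itv = str(rng.choice(["NA", "VUS", "LB", "B"], p=[0.8, 0.1, 0.05, 0.05]))
        hit_genes = genes.genes_at(chrom, pos0)
        variants.append(
            SmallVariant(
                chrom=chrom, pos=pos0 + 1, ref=str(ref), alt=str(alt),
                genotypes={
                    PROBAND: make_member(kid, gq=gq, dp=dp),
                    MOTHER: make_member(mom, gq=90, dp=35),
                    FATHER: make_member(dad, gq=90, dp=35),
                },
                filter_status=filt, popaf=af, consequence=csq,
                clinvar=clv, intervar=itv,
                gene=sorted(hit_genes)[0] if hit_genes else None,
            )
        )

    # background de novo candidates (rare, unremarkable classification)
    for _ in range(config.n_background_de_novo_snvs):
        chrom = str(rng.choice(["chr1", "chr2"]))
        gene_idx = int(rng.integers(0, 30))
        base = 200_000 + gene_idx * 250_000 + int(rng.integers(0, 200))
        if (chrom, base) in used:
            base += 211
        used.add((chrom, base))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        hit = genes.genes_at(chrom, base)
        variants.append(
            SmallVariant(
                chrom=chrom, pos=base + 1, ref=str(ref), alt=str(alt),
                genotypes={
                    PROBAND: make_member((0, 1), gq=80, dp=30),
                    MOTHER: make_member((0, 0), gq=90, dp=35),
                    FATHER: make_member((0, 0), gq=90, dp=35),
                },
                popaf=float(rng.uniform(1e-5, 0.01)), consequence="nonsynonymous",
                gene=sorted(hit)[0] if hit else None,
            )
        )

    planted: Dict[str, dict] = {}

    # de novo pathogenic SNV in DNGENE
    dn_pos0 = 9_000_100
    variants.append(
        SmallVariant(
            chrom="chr1", pos=dn_pos0 + 1, ref="A", alt="T",
            genotypes={
                PROBAND: make_member((0, 1), gq=99, dp=40),
                MOTHER: make_member((0, 0), gq=95, dp=38),
                FATHER: make_member((0, 0), gq=96, dp=41),
            },
            popaf=None, consequence="stopgain", clinvar="P", intervar="P",
            gene="DNGENE",
        )
    )
    planted["de_novo_snv"] = {
        "chrom": "chr1", "pos": dn_pos0 + 1, "gene": "DNGENE",
        "group": "de_novo",
    }

    # compound-het pair in trans within CHGENE, one allele per parent
    spacing = int(rng.integers(50_000, 200_001))
    ch1 = 8_410_000
    ch2 = ch1 + spacing
    phase_set = str(ch1 + 1)
    variants.append(
        SmallVariant(
            chrom="chr1", pos=ch1 + 1, ref="C", alt="CGGCCCCCGG",
            genotypes={
                PROBAND: make_member((1, 0), phased=True, gq=99, dp=42),
                MOTHER: make_member((0, 1), gq=92, dp=36),
                FATHER: make_member((0, 0), gq=93, dp=33),
            },
            popaf=0.0002, consequence="frameshift", clinvar="P", intervar="LP",
            phase_set=phase_set, haplotype_index=1, gene="CHGENE",
        )
    )
    variants.append(
        SmallVariant(
            chrom="chr1", pos=ch2 + 1, ref="G", alt="A",
            genotypes={
                PROBAND: make_member((0, 1), phased=True, gq=98, dp=39),
                MOTHER: make_member((0, 0), gq=91, dp=37),
                FATHER: make_member((0, 1), gq=94, dp=34),
            },
            popaf=0.0001, consequence="stopgain", clinvar="NA", intervar="VUS",
            phase_set=phase_set, haplotype_index=2, gene="CHGENE",
        )
    )
    planted["compound_het"] = {
        "chrom": "chr1", "pos1": ch1 + 1, "pos2": ch2 + 1,
        "spacing": spacing, "gene": "CHGENE", "phase_set": phase_set,
        "group": "compound_het",
    }
    return variants, planted


# ---------------------------------------------------------------------------
# structural variants

def _in_exclusion(chrom: str, start: int, end: int) -> bool:
    return any(start < z2 and end > z1 for z1, z2 in _EXCLUSION[chrom])


@dataclass
class SvFixture:
    proband_smap: List[StructuralVariant] = field(default_factory=list)
    mother_smap: List[StructuralVariant] = field(default_factory=list)
    father_smap: List[StructuralVariant] = field(default_factory=list)
    tenx_large: List[StructuralVariant] = field(default_factory=list)
    tenx_dels: List[StructuralVariant] = field(default_factory=list)
    panel: List[StructuralVariant] = field(default_factory=list)
    cohort: List[StructuralVariant] = field(default_factory=list)
    planted: Dict[str, dict] = field(default_factory=dict)


def simulate_trio_svs(config: SimulationConfig) -> SvFixture:
    """Background SV call sets with panel/parent sharing plus planted events."""
    rng = _rng(config, 3)
    fx = SvFixture()
    counter = [0]

    def new_id(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]:04d}"

    def draw_interval(rng) -> Tuple[str, int, int]:
        while True:
            chrom = str(rng.choice(["chr1", "chr2"]))
            start = int(rng.integers(100_000, 7_400_000))
            size = int(rng.integers(5_000, 100_000))
            if not _in_exclusion(chrom, start, start + size):
                return chrom, start, start + size

    def jitter(pos: int) -> int:
        return max(0, pos + int(rng.integers(-100, 101)))

    panel_samples = [f"PANEL{j:03d}" for j in range(config.panel_size)]
    cohort_samples = [f"CASE{j:03d}" for j in range(config.cohort_size)]

    for i in range(config.n_background_svs):
        chrom, start, end = draw_interval(rng)
        sv_type = str(rng.choice(
            ["deletion", "insertion", "duplication"], p=[0.4, 0.3, 0.3]
        ))
        conf = float(rng.uniform(0.3, 0.99))
        sv = StructuralVariant(
            id=new_id("om"), sv_type=sv_type, chrom1=chrom, pos1=start,
            chrom2=chrom, pos2=end, confidence=round(conf, 3),
            source="optical_map", zygosity="het",
        )
        fx.proband_smap.append(sv)
        if rng.random() < config.panel_share_rate:
            for s in rng.choice(panel_samples, size=3, replace=False):
                fx.panel.append(StructuralVariant(
                    id=new_id("pn"), sv_type=sv_type, chrom1=chrom,
                    pos1=jitter(start), chrom2=chrom, pos2=jitter(end),
                    confidence=0.7, source="optical_map", zygosity="het",
                    sample=str(s),
                ))
        elif i % 5 == 0:
            # private to the family but recurrent in the cohort -> screened out
            for s in rng.choice(cohort_samples, size=3, replace=False):
                fx.cohort.append(StructuralVariant(
                    id=new_id("ch"), sv_type=sv_type, chrom1=chrom,
                    pos1=jitter(start), chrom2=chrom, pos2=jitter(end),
                    confidence=0.7, source="optical_map", zygosity="het",
                    sample=str(s),
                ))
        if rng.random() < config.parent_share_rate:
            fx.mother_smap.append(StructuralVariant(
                id=new_id("mm"), sv_type=sv_type, chrom1=chrom,
                pos1=jitter(start), chrom2=chrom, pos2=jitter(end),
                confidence=0.8, source="optical_map", zygosity="het",
            ))
        if rng.random() < config.parent_share_rate:
            fx.father_smap.append(StructuralVariant(
                id=new_id("ff"), sv_type=sv_type, chrom1=chrom,
                pos1=jitter(start), chrom2=chrom, pos2=jitter(end),
                confidence=0.8, source="optical_map", zygosity="het",
            ))

    # panel-only extras
    for _ in range(40):
        chrom, start, end = draw_interval(rng)
        fx.panel.append(StructuralVariant(
            id=new_id("pn"),
            sv_type=str(rng.choice(["deletion", "insertion", "duplication"])),
            chrom1=chrom, pos1=start, chrom2=chrom, pos2=end,
            confidence=0.7, source="optical_map", zygosity="het",
            sample=str(rng.choice(panel_samples)),
        ))

    # one private inversion and a panel-matched one
    chrom, start, end = draw_interval(rng)
    fx.proband_smap.append(StructuralVariant(
        id=new_id("om"), sv_type="inversion", chrom1=chrom, pos1=start,
        chrom2=chrom, pos2=end, confidence=None, source="optical_map",
    ))
    chrom, start, end = draw_interval(rng)
    fx.proband_smap.append(StructuralVariant(
        id=new_id("om"), sv_type="inversion", chrom1=chrom, pos1=start,
        chrom2=chrom, pos2=end, confidence=None, source="optical_map",
    ))
    fx.panel.append(StructuralVariant(
        id=new_id("pn"), sv_type="inversion", chrom1=chrom, pos1=jitter(start),
        chrom2=chrom, pos2=jitter(end), confidence=0.7, source="optical_map",
        sample=str(rng.choice(panel_samples)),
    ))

    # linked-read background: unknown / inversion / breakend pairs / dels
    for _ in range(10):
        chrom, start, end = draw_interval(rng)
        fx.tenx_large.append(StructuralVariant(
            id=new_id("lu"), sv_type="unknown", chrom1=chrom, pos1=start,
            chrom2=chrom, pos2=end, quality=round(float(rng.uniform(1, 5)), 2),
            source="linked_read",
        ))
    for _ in range(8):
        c1, s1, _ = draw_interval(rng)
        c2, s2, _ = draw_interval(rng)
        if c1 == c2 and s2 < s1:
            s1, s2 = s2, s1
        fx.tenx_large.append(StructuralVariant(
            id=new_id("lb"), sv_type="breakend", chrom1=c1, pos1=s1,
            chrom2=c2, pos2=s2, quality=round(float(rng.uniform(2, 5)), 2),
            source="linked_read",
        ))
    for _ in range(8):
        chrom, start, end = draw_interval(rng)
        sv = StructuralVariant(
            id=new_id("ld"), sv_type="deletion", chrom1=chrom, pos1=start,
            chrom2=chrom, pos2=end, quality=round(float(rng.uniform(10, 60)), 1),
            source="linked_read", zygosity="het",
        )
        fx.tenx_dels.append(sv)
        if rng.random() < 0.4:
            fx.panel.append(StructuralVariant(
                id=new_id("pn"), sv_type="deletion", chrom1=chrom,
                pos1=jitter(start), chrom2=chrom, pos2=jitter(end),
                confidence=0.7, source="optical_map", zygosity="het",
                sample=str(rng.choice(panel_samples)),
            ))

    # ---- planted events -------------------------------------------------
    dchrom, dstart, dend = DUP_BREAKPOINTS
    dup_id = new_id("om")
    fx.proband_smap.append(StructuralVariant(
        id=dup_id, sv_type="duplication", chrom1=dchrom, pos1=dstart,
        chrom2=dchrom, pos2=dend, confidence=0.8, source="optical_map",
        zygosity="het",
    ))
    dup_lr_id = new_id("lg")
    fx.tenx_large.append(StructuralVariant(
        id=dup_lr_id, sv_type="duplication", chrom1=dchrom, pos1=dstart,
        chrom2=dchrom, pos2=dend, quality=60.0, source="linked_read",
        zygosity="het",
    ))
    fx.planted["duplication"] = {
        "id": dup_id, "linked_read_id": dup_lr_id, "chrom": dchrom,
        "start": dstart, "end": dend, "length": dend - dstart,
        "gene": "DUPGENE", "group": "sv_optical_duplication",
        "linked_group": "sv_linked_duplication",
    }

    echrom, estart, eend = DEL_BREAKPOINTS
    del_id = new_id("om")
    fx.proband_smap.append(StructuralVariant(
        id=del_id, sv_type="deletion", chrom1=echrom, pos1=estart,
        chrom2=echrom, pos2=eend, confidence=0.9, source="optical_map",
        zygosity="hom",
    ))
    fx.mother_smap.append(StructuralVariant(
        id=new_id("mm"), sv_type="deletion", chrom1=echrom, pos1=estart + 50,
        chrom2=echrom, pos2=eend + 40, confidence=0.85, source="optical_map",
        zygosity="het",
    ))
    fx.father_smap.append(StructuralVariant(
        id=new_id("ff"), sv_type="deletion", chrom1=echrom, pos1=estart - 30,
        chrom2=echrom, pos2=eend - 20, confidence=0.88, source="optical_map",
        zygosity="het",
    ))
    fx.planted["biallelic_deletion"] = {
        "id": del_id, "chrom": echrom, "start": estart, "end": eend,
        "length": eend - estart, "gene": "DELGENE",
        "group": "sv_optical_deletion",
    }

    tc1, tp1, tc2, tp2 = TRANSLOC_BREAKPOINTS
    tr_id = new_id("om")
    fx.proband_smap.append(StructuralVariant(
        id=tr_id, sv_type="translocation", chrom1=tc1, pos1=tp1,
        chrom2=tc2, pos2=tp2, confidence=None, source="optical_map",
    ))
    bnd_id = new_id("lb")
    fx.tenx_large.append(StructuralVariant(
        id=bnd_id, sv_type="breakend", chrom1=tc1, pos1=tp1,
        chrom2=tc2, pos2=tp2, quality=30.0, source="linked_read",
    ))
    fx.planted["translocation"] = {
        "id": tr_id, "linked_read_id": bnd_id,
        "chrom1": tc1, "pos1": tp1, "chrom2": tc2, "pos2": tp2,
        "genes": ["TRGENE1", "TRGENE2"], "group": "sv_optical_translocation",
        "linked_group": "sv_linked_breakend",
    }
    return fx


# ---------------------------------------------------------------------------
# full fixture directory

def _write_syndrome_bed(path) -> None:
    rows = [
        ("chr2", 8_000_000, 8_060_000, "dup_syndrome_2q:duplication"),
        ("chr2", 8_590_000, 8_660_000, "del_syndrome_2q:deletion"),
        ("chr1", 1_000_000, 1_500_000, "del_syndrome_1p:deletion"),
        ("chr1", 2_000_000, 2_400_000, "dup_syndrome_1p:duplication"),
    ]
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def _write_ontology(ontology: Ontology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tname\tparent_ids\n")
        for term in sorted(ontology, key=lambda t: t.id):
            fh.write(f"{term.id}\t{term.name}\t{'|'.join(sorted(term.parents))}\n")


def _write_annotations(annotations: PhenotypeAnnotationMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tgene_symbol\n")
        for term in sorted(annotations.term_to_genes):
            for gene in sorted(annotations.term_to_genes[term]):
                fh.write(f"{term}\t{gene}\n")


def simulate_case(config: SimulationConfig, outdir) -> dict:
    """Emit the complete fixture directory and return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    ontology, annotations, curated, nlp = make_toy_ontology_and_annotations(config)
    _write_ontology(ontology, out / "ontology.tsv")
    _write_annotations(annotations, out / "gene_annotations.tsv")
    with open(out / "phenome.json", "w", encoding="utf-8") as fh:
        json.dump({"curated_hpo": curated, "nlp_hpo": nlp}, fh, indent=2)
        fh.write("\n")

    _write_features(gene_spans(), out / "genes.tsv")
    _write_features(exon_spans(), out / "exons.tsv")
    _write_syndrome_bed(out / "syndromes.bed")

    variants, planted_small = simulate_trio_small_variants(config)
    vio.write_trio_vcf(variants, out / "trio.vcf", CONTIGS)

    fx = simulate_trio_svs(config)
    vio.write_smap(fx.proband_smap, out / "proband.smap")
    vio.write_smap(fx.mother_smap, out / "mother.smap")
    vio.write_smap(fx.father_smap, out / "father.smap")
    vio.write_smap(fx.panel, out / "panel.tsv", with_sample=True)
    vio.write_smap(fx.cohort, out / "cohort.tsv", with_sample=True)
    vio.write_tenx_sv_vcf(fx.tenx_large, out / "large_svs.vcf", CONTIGS)
    vio.write_tenx_sv_vcf(fx.tenx_dels, out / "dels.vcf", CONTIGS)

    manifest = {
        "seed": config.seed,
        "proband_sex": config.proband_sex,
        "files": {
            "ontology": "ontology.tsv",
            "annotations": "gene_annotations.tsv",
            "phenome": "phenome.json",
            "genes": "genes.tsv",
            "exons": "exons.tsv",
            "syndromes": "syndromes.bed",
            "trio_vcf": "trio.vcf",
            "proband_smap": "proband.smap",
            "mother_smap": "mother.smap",
            "father_smap": "father.smap",
            "panel": "panel.tsv",
            "cohort": "cohort.tsv",
            "tenx_large_svs": "large_svs.vcf",
            "tenx_dels": "dels.vcf",
        },
        "planted": {**planted_small, **fx.planted},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
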