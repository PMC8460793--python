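"""Shared builders and fixtures for the test suite."""

from __future__ import annotations

import pytest

from varprio.phenotype import HpoTerm, Ontology, PhenotypeAnnotationMap
from varprio.records import (
    FATHER,
    GenomicInterval,
    MemberGenotype,
    MOTHER,
    PROBAND,
    SmallVariant,
    StructuralVariant,
)


def make_member(alleles, phased=False, gq=99, dp=40):
    return MemberGenotype(tuple(alleles), phased=phased, gq=gq, dp=dp)


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    proband=(0, 1),
    mother=(0, 0),
    father=(0, 0),
    phased=False,
    gq=99,
    dp=40,
    **kwargs,
):
    """A trio SmallVariant with sensible defaults; parents=None -> singleton."""
    genotypes = {PROBAND: make_member(proband, phased=phased, gq=gq, dp=dp)}
    if mother is not None:
        genotypes[MOTHER] = make_member(mother)
    if father is not None:
        genotypes[FATHER] = make_member(father)
    return SmallVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=genotypes, **kwargs
    )


def make_sv(
    id="sv1",
    sv_type="deletion",
    chrom="chr1",
    start=1000,
    end=2000,
    chrom2=None,
    **kwargs,
):
    return StructuralVariant(
        id=id, sv_type=sv_type, chrom1=chrom, pos1=start,
        chrom2=chrom2 or chrom, pos2=end, **kwargs
    )


def interval(chrom, start, end):
    return GenomicInterval(chrom, start, end)


@pytest.fixture
def chain_ontology():
    """A -> B -> C chain (A is the root)."""
    return Ontology([
        HpoTerm("A", "root"),
        HpoTerm("B", "mid", {"A"}),
        HpoTerm("C", "leaf", {"B"}),
    ])


@pytest.fixture
def toy_annotations():
    """Gene counts chosen so term weights are 1, 1/2 and 1/4."""
    return PhenotypeAnnotationMap([
        ("C", "GENE1"),
        ("B", "GENE1"), ("B", "GENE2"),
        ("A", "GENE1"), ("A", "GENE2"), ("A", "GENE3"), ("A", "GENE4"),
    ])
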