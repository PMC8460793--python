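"""Readers and writers for the pipeline's external formats.

Supported formats: trio small-variant VCF 4.2 (with genotype quality,
depth and phase-set FORMAT fields plus pre-computed annotation INFO
fields), SMAP-style optical-map SV tables, linked-read SV VCF dialects
("dels" and "large_svs"), reference-panel / cohort tables (SMAP columns
plus a sample id), syndrome-region BED4, gene/exon feature TSVs, the
patient phenome JSON, and the tab-delimited report.

All coordinates are converted to the internal 0-based convention on
read (see :mod:`varprio.records`) and back on write.
"""

from __future__ import annotations

import json
import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .records import (
    FATHER,
    GenomicInterval,
    MemberGenotype,
    MOTHER,
    PROBAND,
    PrioritizedCall,
    ReferenceSvPanel,
    SmallVariant,
    StructuralVariant,
    SyndromeRegion,
    TRIO_ROLES,
)

logger = logging.getLogger(__name__)

#: Default INFO-key names for the pre-computed annotation fields.  Real
#: annotation pipelines use different keys; override via ``info_keys``.
DEFAULT_INFO_KEYS = {
    "popaf": "POPAF",
    "consequence": "CSQCLS",
    "clinvar": "CLNVR",
    "intervar": "INTVR",
    "gene": "GENE",
}

SMAP_REQUIRED_COLUMNS = (
    "SmapEntryID",
    "RefcontigID1",
    "RefcontigID2",
    "RefStartPos",
    "RefEndPos",
    "Confidence",
    "Type",
    "Zygosity",
)


# ---------------------------------------------------------------------------
# trio small-variant VCF

def _decompose_gt(raw: tuple, phased: bool, alt_index: int,
                  gq, dp) -> MemberGenotype:
    """Project a (possibly multi-allelic) GT onto one ALT allele."""
    alleles = tuple(
        None if a is None else (1 if a == alt_index else 0) for a in raw
    )
    return MemberGenotype(
        alleles=alleles,
        phased=phased,
        gq=None if gq is None else int(gq),
        dp=None if dp is None else int(dp),
    )


def _per_alt(value, alt_index: int):
    """Pick the per-ALT entry from a Number=A INFO value."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if alt_index - 1 < len(value):
            return value[alt_index - 1]
        return None
    return value


def read_trio_vcf(
    path,
    sample_roles: Mapping[str, str],
    info_keys: Optional[Mapping[str, str]] = None,
) -> List[SmallVariant]:
    """Read a trio (or singleton) VCF into decomposed SmallVariant records.

    ``sample_roles`` maps role (proband/mother/father) to the VCF sample
    name; the proband is mandatory, parents optional (singleton mode).
    Multi-allelic sites yield one record per ALT allele; alleles other
    than the focal ALT are projected to reference.  Missing annotation
    INFO fields map to NA/absent.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    if PROBAND not in sample_roles:
        raise ValueError("sample_roles must name a proband sample")

    variants: List[SmallVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        present = set(vcf.header.samples)
        for role, sample in sample_roles.items():
            if sample not in present:
                raise ValueError(
                    f"required sample {sample!r} (role {role}) absent from {path}"
                )
        for rec in vcf:
            alts = rec.alts or ()
            filt = list(rec.filter.keys())
            filter_status = ";".join(filt) if filt else "PASS"
            for alt_index, alt in enumerate(alts, start=1):
                genotypes: Dict[str, MemberGenotype] = {}
                for role, sample in sample_roles.items():
                    s = rec.samples[sample]
                    genotypes[role] = _decompose_gt(
                        s.get("GT", ()), s.phased, alt_index,
                        s.get("GQ"), s.get("DP"),
                    )
                pro = rec.samples[sample_roles[PROBAND]]
                ps = pro.get("PS")
                phase_set = None if ps is None else str(ps)
                hap = None
                gt = genotypes[PROBAND]
                if phase_set is not None and gt.phased and gt.is_het:
                    hap = 1 if gt.alleles[0] == 1 else 2
                popaf = _per_alt(rec.info.get(keys["popaf"]), alt_index)
                csq = _per_alt(rec.info.get(keys["consequence"]), alt_index)
                clv = _per_alt(rec.info.get(keys["clinvar"]), alt_index)
                itv = _per_alt(rec.info.get(keys["intervar"]), alt_index)
                gene = rec.info.get(keys["gene"])
                variants.append(
                    SmallVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotypes=genotypes,
                        filter_status=filter_status,
                        popaf=None if popaf is None else float(popaf),
                        consequence=csq or "other",
                        clinvar=clv or "NA",
                        intervar=itv or "NA",
                        phase_set=phase_set,
                        haplotype_index=hap,
                        gene=None if gene in (None, ".", "") else str(gene),
                    )
                )
    return variants


def write_trio_vcf(
    variants: Sequence[SmallVariant],
    path,
    contigs: Mapping[str, int],
    sample_roles: Optional[Mapping[str, str]] = None,
    info_keys: Optional[Mapping[str, str]] = None,
) -> None:
    """Write biallelic SmallVariant records as an uncompressed VCF."""
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    roles = sample_roles or {r: r.upper() for r in TRIO_ROLES}
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.filters.add("LOWQ", None, None, "Low-quality call")
    header.info.add(keys["popaf"], "A", "Float", "Population allele frequency")
    header.info.add(keys["consequence"], "A", "String", "Consequence class")
    header.info.add(keys["clinvar"], "A", "String", "ClinVar classification")
    header.info.add(keys["intervar"], "A", "String", "Intervar classification")
    header.info.add(keys["gene"], "1", "String", "Gene symbol")
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("GQ", "1", "Integer", "Genotype quality")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.formats.add("PS", "1", "Integer", "Phase set")
    for role in roles:
        header.add_sample(roles[role])

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.filter_status and v.filter_status != "PASS":
                for f in v.filter_status.split(";"):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            if v.popaf is not None:
                rec.info[keys["popaf"]] = (v.popaf,)
            rec.info[keys["consequence"]] = (v.consequence,)
            rec.info[keys["clinvar"]] = (v.clinvar,)
            rec.info[keys["intervar"]] = (v.intervar,)
            if v.gene:
                rec.info[keys["gene"]] = v.gene
            for role, sample in roles.items():
                gt = v.member(role)
                s = rec.samples[sample]
                if gt is None or gt.is_missing:
                    s["GT"] = (None, None)
                    continue
                s["GT"] = gt.alleles
                s.phased = gt.phased
                if gt.gq is not None:
                    s["GQ"] = gt.gq
                if gt.dp is not None:
                    s["DP"] = gt.dp
                if role == PROBAND and v.phase_set is not None:
                    s["PS"] = int(v.phase_set)
            out.write(rec)


# ---------------------------------------------------------------------------
# SMAP optical-map tables

def _map_smap_type(raw: str) -> str:
    t = raw.strip().lower()
    for prefix, mapped in (
        ("deletion", "deletion"),
        ("insertion", "insertion"),
        ("duplication", "duplication"),
        ("inversion", "inversion"),
        ("translocation", "translocation"),
    ):
        if t.startswith(prefix):
            return mapped
    return "unknown"


_ZYGOSITY_IN = {"homozygous": "hom", "heterozygous": "het"}
_ZYGOSITY_OUT = {"hom": "homozygous", "het": "heterozygous",
                 "unknown": "unknown"}


def _read_hash_header_table(path) -> List[Dict[str, str]]:
    """Parse a tab table whose header may be a plain line or Bionano '#h'."""
    header: Optional[List[str]] = None
    rows: List[Dict[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#h"):
                header = line[2:].strip().split("\t")
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append(dict(zip(header, fields)))
    if header is None:
        header = []
    rows_header = header
    missing = [c for c in SMAP_REQUIRED_COLUMNS if c not in rows_header]
    if missing and (rows or rows_header):
        raise ValueError(f"{path}: missing required SMAP columns {missing}")
    return rows


def read_smap(path, source: str = "optical_map") -> List[StructuralVariant]:
    """Read an SMAP-style SV table.

    Bionano's "confidence not computed" convention (Confidence == -1) is
    mapped to an absent confidence, which is exempt from confidence
    thresholds downstream.  An optional ``Sample`` column is carried
    through for panel/cohort files.
    """
    calls: List[StructuralVariant] = []
    for row in _read_hash_header_table(path):
        conf = float(row["Confidence"])
        p1 = int(float(row["RefStartPos"])) - 1
        p2 = int(float(row["RefEndPos"])) - 1
        c1, c2 = str(row["RefcontigID1"]), str(row["RefcontigID2"])
        if c1 == c2 and p2 < p1:
            p1, p2 = p2, p1
        calls.append(
            StructuralVariant(
                id=str(row["SmapEntryID"]),
                sv_type=_map_smap_type(row["Type"]),
                chrom1=c1,
                pos1=p1,
                chrom2=c2,
                pos2=p2,
                confidence=None if conf < 0 else conf,
                source=source,
                zygosity=_ZYGOSITY_IN.get(row["Zygosity"].lower(), "unknown"),
                sample=row.get("Sample") or None,
            )
        )
    return calls


def write_smap(calls: Sequence[StructuralVariant], path,
               with_sample: bool = False) -> None:
    """Write SVs in the SMAP-style tab dialect (1-based coordinates)."""
    cols = list(SMAP_REQUIRED_COLUMNS) + (["Sample"] if with_sample else [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for sv in calls:
            row = [
                sv.id,
                sv.chrom1,
                sv.chrom2,
                str(sv.pos1 + 1),
                str(sv.pos2 + 1),
                "-1" if sv.confidence is None else f"{sv.confidence:g}",
                sv.sv_type,
                _ZYGOSITY_OUT.get(sv.zygosity, "unknown"),
            ]
            if with_sample:
                row.append(sv.sample or "")
            fh.write("\t".join(row) + "\n")


def read_panel(path) -> ReferenceSvPanel:
    """Read a panel/cohort file (SMAP dialect plus Sample column)."""
    return ReferenceSvPanel(read_smap(path))


# ---------------------------------------------------------------------------
# linked-read SV VCF dialects

_SVTYPE_MAP = {
    "DEL": "deletion",
    "DUP": "duplication",
    "DUP:TANDEM": "duplication",
    "INS": "insertion",
    "INV": "inversion",
    "BND": "breakend",
    "UNK": "unknown",
}


def _parse_bnd_alt(alt: str) -> Optional[Tuple[str, int]]:
    """Extract (chrom, 0-based pos) from a BND mate ALT string."""
    for br in ("[", "]"):
        if br in alt:
            inner = alt.split(br)[1]
            if ":" in inner:
                chrom, pos = inner.rsplit(":", 1)
                return chrom, int(pos) - 1
    return None


def read_tenx_sv_vcf(path, dialect: str) -> List[StructuralVariant]:
    """Read a linked-read SV VCF ("dels" or "large_svs" dialect).

    BND records are paired by MATEID into a single breakend SV; an
    unpaired BND is kept single-ended with a warning.  Records without
    SVTYPE map to sv_type "unknown".
    """
    if dialect not in ("dels", "large_svs"):
        raise ValueError(f"unknown linked-read SV dialect {dialect!r}")
    simple: List[StructuralVariant] = []
    bnds: Dict[str, pysam.VariantRecord] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            mapped = _SVTYPE_MAP.get(svtype, "unknown") if svtype else "unknown"
            zyg = "unknown"
            if len(rec.samples) > 0:
                gt = rec.samples[0].get("GT", ())
                called = [a for a in gt if a is not None]
                if called:
                    zyg = "hom" if all(a >= 1 for a in called) and len(called) > 1 \
                        else "het"
            if mapped == "breakend":
                bnds[rec.id or f"bnd_{len(bnds)}"] = rec
                continue
            pos1 = rec.pos - 1
            pos2 = rec.stop - 1  # pysam surfaces INFO/END as rec.stop
            if pos2 < pos1:
                pos1, pos2 = pos2, pos1
            simple.append(
                StructuralVariant(
                    id=rec.id or f"{rec.chrom}_{rec.pos}",
                    sv_type=mapped,
                    chrom1=rec.chrom,
                    pos1=pos1,
                    chrom2=rec.chrom,
                    pos2=pos2,
                    quality=None if rec.qual is None else float(rec.qual),
                    source="linked_read",
                    zygosity=zyg,
                )
            )
    # pair breakends by MATEID
    consumed: set = set()
    for rid, rec in bnds.items():
        if rid in consumed:
            continue
        mate_id = rec.info.get("MATEID")
        if isinstance(mate_id, tuple):
            mate_id = mate_id[0] if mate_id else None
        mate = bnds.get(mate_id) if mate_id else None
        event_id = rid
        if mate is not None and mate_id not in consumed:
            consumed.update({rid, mate_id})
            chrom2, pos2 = mate.chrom, mate.pos - 1
            # mates named <event>_1/<event>_2 collapse to the event id
            if (rid[-2:] in ("_1", "_2") and mate_id[-2:] in ("_1", "_2")
                    and rid[:-2] == mate_id[:-2]):
                event_id = rid[:-2]
        else:
            consumed.add(rid)
            parsed = _parse_bnd_alt(rec.alts[0]) if rec.alts else None
            if parsed is None:
                logger.warning("unpaired breakend %s with unparseable mate", rid)
                chrom2, pos2 = rec.chrom, rec.pos - 1
            else:
                logger.warning("unpaired breakend %s; using ALT coordinates", rid)
                chrom2, pos2 = parsed
        chrom1, pos1 = rec.chrom, rec.pos - 1
        if chrom1 == chrom2 and pos2 < pos1:
            pos1, pos2 = pos2, pos1
        simple.append(
            StructuralVariant(
                id=event_id,
                sv_type="breakend",
                chrom1=chrom1,
                pos1=pos1,
                chrom2=chrom2,
                pos2=pos2,
                quality=None if rec.qual is None else float(rec.qual),
                source="linked_read",
            )
        )
    return simple


def write_tenx_sv_vcf(
    calls: Sequence[StructuralVariant], path, contigs: Mapping[str, int]
) -> None:
    """Write SVs in the linked-read VCF dialect (BND pairs for breakends)."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("SVTYPE", "1", "String", "Type of structural variant")
    header.info.add("END", "1", "Integer", "End position of the variant")
    header.info.add("MATEID", "1", "String", "ID of mate breakend")
    rev = {v: k for k, v in _SVTYPE_MAP.items() if k != "DUP:TANDEM"}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for sv in calls:
            if sv.sv_type == "breakend":
                for suffix, (c1, p1, c2, p2) in (
                    ("_1", (sv.chrom1, sv.pos1, sv.chrom2, sv.pos2)),
                    ("_2", (sv.chrom2, sv.pos2, sv.chrom1, sv.pos1)),
                ):
                    rec = out.new_record(
                        contig=c1, start=p1, stop=p1 + 1,
                        alleles=("N", f"N[{c2}:{p2 + 1}["),
                    )
                    rec.id = sv.id + suffix
                    rec.info["SVTYPE"] = "BND"
                    rec.info["MATEID"] = sv.id + ("_2" if suffix == "_1" else "_1")
                    if sv.quality is not None:
                        rec.qual = sv.quality
                    out.write(rec)
                continue
            rec = out.new_record(
                contig=sv.chrom1, start=sv.pos1, stop=sv.pos2 + 1,
                alleles=("N", f"<{rev[sv.sv_type]}>"),
            )
            rec.id = sv.id
            rec.info["SVTYPE"] = rev[sv.sv_type]
            if sv.quality is not None:
                rec.qual = sv.quality
            out.write(rec)


# ---------------------------------------------------------------------------
# syndrome regions, feature maps, phenome JSON

def read_syndrome_bed(path) -> List[SyndromeRegion]:
    """Read microdeletion/microduplication syndrome regions from BED4.

    The name field carries ``name:expected_type`` with expected_type in
    {deletion, duplication}.  BED coordinates are already 0-based
    half-open.
    """
    regions: List[SyndromeRegion] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name_field = line.split("\t")[:4]
            name, _, expected = name_field.rpartition(":")
            regions.append(
                SyndromeRegion(
                    name=name or name_field,
                    interval=GenomicInterval(chrom, int(start), int(end)),
                    expected_type=expected,
                )
            )
    return regions


class FeatureMap:
    """Interval lookup of named genomic features (gene spans or exons)."""

    def __init__(self, features: Iterable[Tuple[GenomicInterval, str]]):
        self._trees: Dict[str, IntervalTree] = {}
        for iv, gene in features:
            if iv.length <= 0:
                continue
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, gene
            )

    @classmethod
    def from_tsv(cls, path) -> "FeatureMap":
        """Read a feature TSV: chrom, start, end, gene (0-based half-open)."""
        feats = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["chrom", "start", "end", "gene"]:
                raise ValueError(
                    f"{path}: feature TSV must start with chrom/start/end/gene"
                )
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, gene = line.rstrip("\n").split("\t")[:4]
                feats.append((GenomicInterval(chrom, int(start), int(end)), gene))
        return cls(feats)

    def genes_overlapping(self, interval: GenomicInterval) -> set:
        tree = self._trees.get(interval.chrom)
        if tree is None or interval.length == 0:
            return set()
        return {hit.data for hit in tree.overlap(interval.start, interval.end)}

    def genes_at(self, chrom: str, pos: int) -> set:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.at(pos)}


def load_phenome_json(path) -> Tuple[List[str], List[str]]:
    """Read the patient phenome JSON: curated and NLP-derived term lists."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return list(doc.get("curated_hpo", [])), list(doc.get("nlp_hpo", []))


# ---------------------------------------------------------------------------
# lengths and display

def sv_length(sv: StructuralVariant) -> Optional[int]:
    """Span of an intrachromosomal SV in bp; absent for translocations.

    With breakpoints stored as points, the span is ``pos2 - pos1`` —
    the convention that reproduces published clinical SV sizes from
    their breakpoint coordinates.
    """
    return sv.length


def format_length(n_bp: int, unit: str = "auto") -> str:
    """Render a bp span at conventional display precision.

    ``auto`` chooses bp below 10 kb, whole kb below 1 Mb, and 0.1-Mb
    precision above (e.g. 32,037 -> "32 kb"; 15,126,176 -> "15.1 Mb").
    """
    if unit == "auto":
        if n_bp >= 1_000_000:
            unit = "Mb"
        elif n_bp >= 10_000:
            unit = "kb"
        else:
            unit = "bp"
    if unit == "Mb":
        return f"{n_bp / 1_000_000:.1f} Mb"
    if unit == "kb":
        return f"{round(n_bp / 1000)} kb"
    if unit == "bp":
        return f"{n_bp} bp"
    raise ValueError(f"unknown unit {unit!r}")


# ---------------------------------------------------------------------------
# report

REPORT_ANNOTATION_COLUMNS = [
    "Found_in_Mother",
    "Found_in_Father",
    "Gene",
    "Phenotype",
    "Gene2",
    "Phenotype2",
    "inheritance_group",
    "rank",
    "gene_sum_score",
    "normalized_score",
]

_REPORT_CALLER_COLUMNS = [
    "id", "source", "variant_type", "chrom", "pos", "chrom2", "pos2",
    "ref", "alt", "length", "confidence", "quality", "zygosity",
    "syndrome_hits", "partner",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def calls_to_frame(calls: Sequence[PrioritizedCall]) -> pd.DataFrame:
    """Flatten prioritized calls to the report table (all-string cells)."""
    rows = []
    for c in calls:
        v = c.variant
        row = dict.fromkeys(_REPORT_CALLER_COLUMNS + REPORT_ANNOTATION_COLUMNS, "")
        if isinstance(v, StructuralVariant):
            row.update(
                id=v.id, source=v.source, variant_type=v.sv_type,
                chrom=v.chrom1, pos=str(v.pos1 + 1),
                chrom2=v.chrom2, pos2=str(v.pos2 + 1),
                length="" if v.length is None else str(v.length),
                confidence=_fmt(v.confidence), quality=_fmt(v.quality),
                zygosity=v.zygosity,
            )
        else:
            row.update(
                id=f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}", source="small_variant",
                variant_type=v.consequence, chrom=v.chrom, pos=str(v.pos),
                ref=v.ref, alt=v.alt,
            )
            if c.partner is not None:
                p = c.partner
                row["partner"] = f"{p.chrom}:{p.pos}:{p.ref}>{p.alt}"
        row["syndrome_hits"] = ";".join(c.syndrome_hits)
        row["Found_in_Mother"] = _fmt(c.found_in_mother)
        row["Found_in_Father"] = _fmt(c.found_in_father)
        row["Gene"] = c.gene
        row["Phenotype"] = c.phenotype
        row["Gene2"] = c.gene2
        row["Phenotype2"] = c.phenotype2
        row["inheritance_group"] = _fmt(c.group)
        row["rank"] = _fmt(c.rank)
        row["gene_sum_score"] = f"{c.gene_sum_score:g}"
        row["normalized_score"] = f"{c.normalized_score:g}"
        rows.append(row)
    return pd.DataFrame(
        rows, columns=_REPORT_CALLER_COLUMNS + REPORT_ANNOTATION_COLUMNS,
        dtype=str,
    )


def write_report(calls: Sequence[PrioritizedCall], path) -> pd.DataFrame:
    """Write the tab-delimited report; returns the emitted table."""
    frame = calls_to_frame(calls)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def read_report(path) -> pd.DataFrame:
    """Read a report back as an all-string table (round-trip safe)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
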