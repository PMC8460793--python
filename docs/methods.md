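# Methods

This note documents the models, conventions and design choices behind
`varprio`, in the order data flows through the pipeline.

## Phenome assembly and gene scoring

The patient phenome merges two term lists: clinician-curated HPO terms
and terms extracted from the clinical record by NLP. The package
consumes the extracted list as given (JSON with `curated_hpo` and
`nlp_hpo` arrays); running the NLP itself is out of scope. Duplicates
collapse with curated provenance winning; term ids absent from the
loaded ontology are dropped with a warning rather than failing the
case.

**One-degree expansion.** The phenome is expanded by the terms at graph
distance 1 from each input term. We expand to *direct parents only*,
not children: generalizing an observed phenotype (patient has
"syndactyly" ⇒ "abnormal digit morphology") is safe, whereas
specializing would assert findings never observed. Grandparents are not
reached — expansion is a single step, not an ancestor closure — and
expanded terms contribute to scoring with full weight; no discount
factor is applied, because none is defined by the weighting model.

**Term weight.** `weight(h) = 1 / |genes(h)|` over the gene–phenotype
annotation map. The weight lies in (0, 1]; it is undefined for terms
annotated to no gene. Such terms carry the "no-weight" sentinel and are
excluded from scoring rather than raising an error — exclusion is the
conservative reading of an undefined ratio, and these terms cannot
discriminate genes anyway.

**Gene sum score and normalization.** A gene scores the sum of weights
over the phenome terms annotated to it. Ranking is by descending score
with lexicographic tie-break on the symbol (determinism). Normalization
divides by the maximum sum score across all scored genes, so the best
match of a case always scores exactly 1; the all-zero case maps to all
zeros. The normalized score doubles as the per-call confidence score
attached in the report.

## Coordinate conventions and SV length

Internally every interval is 0-based half-open; VCF and SMAP positions
(1-based) are converted on read and back on write, and the conversion
is bijective. SV breakpoints are stored as 0-based *points*, so the
span of an intrachromosomal event is `pos2 − pos1` — end − start, not
end − start + 1. This convention is a deliberate choice: it reproduces
published clinical SV sizes exactly from their printed breakpoint
pairs (e.g. chr10:28615989–28617469 → 1480 bp;
chr2:61210747–61215747 → 5000 bp), which the regression table in the
test suite and `varprio.casetable.printed_size_checks()` pin down.
Display rounding is to the conventional precision: whole kb from 10 kb
(32,037 → "32 kb") and 0.1 Mb above 1 Mb (15,126,176 → "15.1 Mb").

SMAP `Confidence = −1` (the optical-map caller's "not computed"
convention) maps to an absent confidence, which is exempt from
confidence thresholds. Multi-allelic VCF sites are decomposed into one
record per ALT allele, with Number=A annotations taken per ALT and
other ALT alleles projected to reference.

## Small-variant stream

Filters, in order (though the result is order-independent — each
filter is a pure subset selection, so they commute and are idempotent):

| filter | rule | default | rationale |
|---|---|---|---|
| prefilter | proband GQ ≥ `gq_min`, DP ≥ `dp_min`, FILTER = PASS | 20 / 10 / on | conventional clinical thresholds; the source fields are standard, the cutoffs are configurable |
| frequency | popAF ≤ `af_max`, absent kept | 0.05 | absence from the population database cannot mean common; novel variants are the most interesting |
| benign exclusion | drop if ClinVar ∈ {B, LB} **or** Intervar ∈ {B, LB} | — | "either" reads as OR |
| consequence | keep frameshift, nonframeshift, nonsynonymous, stopgain, stoploss, splicing | — | protein-relevant classes only |

All boundaries are inclusive (GQ = 20 passes; popAF = 0.05 passes).

**Inheritance partitioning.** Trio genotypes assign candidates to de
novo (proband carries, both parents homozygous reference), homozygous
recessive (proband hom-alt, both parents het), compound het (≥ 2
proband-het variants in one gene, one allele from each parent *or* in
trans by phase), X-linked (single-X proband, set by the
`proband_sex` flag), and dominant inherited (het shared with exactly
one parent). A variant may appear in several groups. Singleton mode is
supported: with no parental genotypes, only the groups that need none
are produced — phase-based compound hets and hemizygous X-linked
candidates.

**Phase.** Two proband variants in the same phase set are *cis* when
their haplotype indices agree and *trans* otherwise; different or
absent phase sets give *unknown*. Trans-by-phase is what lets a
compound het be called from the proband alone.

**Ranking.** Within a group the sort key is (pathogenicity tier:
P > LP > everything else; then gene sum score descending; then genomic
position). When curated and computed classifications disagree, the
curated one wins — a curated assertion outranks a computed one.
Compound-het pairs are ranked by their best member and reported as a
single row with the partner's coordinates attached, keeping ranks
unique within the group.

## Structural-variant stream

Matching is type-stratified throughout: deletions only match
deletions, etc.

**Reciprocal overlap** (deletions, insertions, duplications): two
same-chromosome intervals match at fraction *f* when the shared span
covers ≥ *f* of each (inclusive boundary; default 0.5). Zero-length
intervals never match. Optical-map calls additionally require
confidence ≥ 0.5 (calls without a reported confidence are exempt).

**Breakpoint intervals** (inversions, translocations, unknown,
breakends): windows are centered on each breakpoint with a *total*
width of 20 kb (optical map) or 10 kb (linked read). The width-versus-
half-width reading of "N kb intervals around the point" is genuinely
ambiguous; we chose total width (±N/2) and expose it
(`--bionano-interval-bp`, `--tenx-interval-bp`). A reference call
matches only when *both* of its breakpoints fall in the corresponding
windows of the *same* event; either-end matching would spuriously
remove novel fusions that share one recurrent breakpoint region.
Surviving inversions and translocations are always carried into the
report regardless of gene overlap.

**Quality outlier rule.** Linked-read unknown and breakend calls keep
only qualities strictly above mean + 1 SD, with the statistics computed
per SV type over the proband's own call set and the *population* SD.
Under the strict inequality a type whose qualities are all identical
keeps nothing (SD = 0); this degenerate case warns.

**Screens.** Deletions/duplications are screened against syndrome
regions with type concordance and any overlap (≥ 1 bp — no fraction is
imposed, since syndrome regions and patient SVs rarely share
breakpoints), and against cohort recurrence: a call is retained when
matched in at most 2 distinct cohort samples. A second control set
(e.g. a population SV database) can be processed as another panel with
the same operation.

**Parental annotation** decorates but never filters:
`Found_in_Mother`/`Found_in_Father` are computed with the same policy
and thresholds as panel removal (the natural default, made explicit
here since nothing forces them to differ). The parents' optical-map
calls also serve as the parental comparison set for the linked-read
stream — matching is interval- and type-based, so the platform of the
comparison call is immaterial. When a parent's call set is not
provided the flags stay empty rather than reading as a spurious
"False".

## Merging and the final report

Small-variant and SV candidates are never ranked against each other on
one scale; each inheritance/SV group is ranked internally (SV groups by
gene score, then position) with contiguous ranks from 1. Calls inherit
the score of their best-scoring overlapped gene — exon-level overlap
for deletions/insertions/duplications, gene-level at both breakpoints
for the rest (`Gene`/`Phenotype` for the start, `Gene2`/`Phenotype2`
for the end). Output is a tab-delimited report plus an optional JSON
group-count summary; identical inputs and configuration produce
byte-identical reports.

## Synthetic fixtures

The simulator emulates the study conditions on a toy genome of three
10-Mb contigs with a fabricated gene/exon map (60 background genes of
20 kb, six planted genes at fixed loci). Per seed it emits a phenotype
ontology (depth-3 DAG, 35 terms; twelve leaves annotated to exactly one
planted gene so their weights are 1.0, mid-level terms carrying 5–20
background genes so weights span the range), a phased trio VCF, SMAP
files for all three family members, linked-read `large_svs`/`dels`
VCFs, a reference panel, a cohort table, a syndrome BED and a manifest
of planted truths.

Background small variants (default 300) draw popAF from a 90%/10%
common/rare mixture (common AF uniform on 5–50%, so most sites are
removed by the frequency filter and the ≤ 5% boundary is exercised);
trio genotypes are Hardy–Weinberg draws for the parents with Mendelian
inheritance for the proband. Background SVs (default 30) share
breakpoints with the panel at rate 0.6 and with each parent at rate
0.4. Five diagnostic events are planted: a de novo pathogenic stopgain
in a phenome-matched gene; a compound-het pair in trans, 50–200 kb
apart in one phase set, one allele from each parent; a 32,037 bp de
novo tandem duplication overlapping exons of a phenome-matched gene,
called by both platforms; a 36,077 bp biallelic deletion (proband
homozygous, both parents heterozygous carriers); and a de novo
translocation between two contigs (optical-map call plus a linked-read
breakend pair, quality 30 against a background of 2–5 so the outlier
rule passes exactly the planted call).

What the simulator does *not* emulate: read-level data, realistic SV
size spectra, genotyping error (background trios are perfectly
Mendelian), mosaicism, segmental-duplication artifacts, or a realistic
17k-term ontology. Passing the recovery tests therefore demonstrates
the pipeline's logic — filters, matching policies, phase arithmetic,
ranking — not calling performance on real data; real annotation
resources can be loaded at run time through the same TSV/VCF adapters.

## Problem sizes and validation

The test suite and the acceptance script use 300 background small
variants and ~30 background SVs per simulated case, 20 seeds for the
recovery check, and 10,000 random interval pairs for the
overlap-oracle check — sizes at which the brute-force oracles
(base-set intersection, all-pairs panel matching, double-loop gene
scoring) remain exact and fast while every filter still has work to
do. Recovery requires each planted event to survive all filters and
rank first in its group — on both platforms where two calls are
planted, with both parental flags set for the biallelic deletion and
neither for the de novo events.

## Known limitations

* Mosaic variants are not flagged (no allele-fraction model).
* Compound-het pairs are ranked against single variants by their best
  member's key; how they should interleave is not otherwise defined.
* The SMAP reader consumes a minimal column subset
  (SmapEntryID, RefcontigID1/2, RefStartPos/EndPos, Confidence, Type,
  Zygosity, optional Sample); caller-specific extra columns are
  ignored.
* Insertion matching when platforms disagree on inserted length uses
  the same reciprocal-overlap rule as deletions; no length-aware
  special case is implemented.
* The X-linked group is produced only when the proband is declared
  male (single X); pseudoautosomal regions are not modeled.
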