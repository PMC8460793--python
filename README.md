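# varprio

Phenotype-driven prioritization of small and structural variants from
trio genomes.

Rare-disease diagnosis from genome data is an "experiment of one": a
proband's genome yields thousands of candidate variants, most of them
irrelevant, and the diagnostic one may be a small variant, a
compound-heterozygous pair, or a structural variant (SV) that short-read
pipelines miss. `varprio` implements an automated interpretation
pipeline for the call sets produced by long-DNA technologies — phased
small-variant VCFs from linked-read sequencing and SV calls from
optical mapping (SMAP tables) and linked-read SV callers (VCF dialects)
— and ranks candidates against the patient's phenotype.

## The scoring model

The patient *phenome* is the union of clinician-curated HPO terms and
terms extracted from the clinical record (consumed as a ready term
list), expanded by one degree up the ontology (direct parents). Each
term *h* is weighted by the inverse of its gene count,

    weight(h) = 1 / |genes(h)|,

so a finding annotated to a single disease gene carries full weight
while an unspecific one is diluted. A gene *G* scores the sum of the
weights of the phenome terms annotated to it,

    score(G) = Σₙ weight(hₙ),   hₙ ∈ phenome ∩ terms(G),

and scores are normalized by the maximum across genes for comparison
across cases. Candidate variants inherit the score of their
best-scoring overlapped gene.

## The filtering pipeline

Small variants: genotype-quality/depth/FILTER prefilter (GQ ≥ 20,
DP ≥ 10, PASS), population allele frequency ≤ 5% (absent = rare),
exclusion of variants called benign/likely benign by *either* a
curated (ClinVar-style) or computed (Intervar-style) classifier, and
restriction to six consequence classes (frameshift, nonframeshift,
nonsynonymous, stopgain, stoploss, splicing). Survivors are partitioned
into inheritance groups — de novo, homozygous recessive, compound
heterozygous (one allele per parent, or in *trans* by haplotype phase
from the proband alone), X-linked, dominant inherited — and ranked by
reported pathogenicity (P > LP > VUS/NA), then gene score.

Structural variants: per-type modules mirror how SV call sets are
compared in practice. Deletions/insertions/duplications are matched by
50% reciprocal overlap (optical-map calls first pass a confidence ≥ 0.5
threshold); inversions, translocations and breakends are matched
through breakpoint windows (20 kb total width for optical-map calls,
10 kb for linked-read calls), with both breakpoints required to hit the
same reference event. Calls matching a reference panel are removed;
parental presence is annotated as `Found_in_Mother`/`Found_in_Father`
without filtering; linked-read unknown/breakend calls must exceed
mean + 1 SD of their type's quality distribution; deletions and
duplications are screened against known
microdeletion/microduplication syndrome regions and against cohort
recurrence (kept when seen in ≤ 2 cohort samples). Inversions and
translocations are always reported.

## Worked example

The package ships a deterministic simulator that emits every input the
pipeline consumes — toy ontology, gene–phenotype map, phased trio VCF,
SMAP files, linked-read SV VCFs, reference panel, cohort, syndrome
BED — with five planted diagnostic events:

```sh
varprio simulate --seed 7 --out demo
varprio report \
    --trio-vcf demo/trio.vcf \
    --proband-smap demo/proband.smap --mother-smap demo/mother.smap \
    --father-smap demo/father.smap \
    --tenx-large-svs demo/large_svs.vcf --tenx-dels demo/dels.vcf \
    --panel demo/panel.tsv --cohort demo/cohort.tsv \
    --syndromes demo/syndromes.bed --exons demo/exons.tsv --genes demo/genes.tsv \
    --ontology demo/ontology.tsv --annotations demo/gene_annotations.tsv \
    --phenome demo/phenome.json \
    --out demo/report.tsv --summary-json demo/summary.json
```

which prints

```
report written to demo/report.tsv (compound_het=1, de_novo=3,
dominant_inherited=4, sv_linked_breakend=1, sv_linked_deletion=8,
sv_linked_duplication=1, sv_linked_unknown=2, sv_optical_deletion=3,
sv_optical_duplication=2, sv_optical_insertion=1, sv_optical_inversion=1,
sv_optical_translocation=1)
```

The rank-1 rows of `demo/report.tsv` are the five planted events, each
at the top of its group:

| group | rank-1 call | Gene | Found_in_Mother/Father |
|---|---|---|---|
| de_novo | chr1:9000101 A>T stopgain | DNGENE | False / False |
| compound_het | chr1:8410001 frameshift (+ partner in *trans*) | CHGENE | True / False |
| sv_optical_duplication | om0193, 32,037 bp duplication | DUPGENE | False / False |
| sv_optical_deletion | om0195, homozygous deletion | DELGENE | True / True |
| sv_optical_translocation | om0198, chr1↔chr2 | TRGENE1/TRGENE2 | False / False |

The duplication and the translocation also top their linked-read
groups (`sv_linked_duplication`, `sv_linked_breakend`), emulating an
event detected by both platforms. `gene_sum_score = 2` is the planted
genes' phenome score (two dedicated terms of weight 1.0);
`normalized_score = 1` marks the best phenotype match of the case.
Background calls that survive the panel either score 0 or carry the
diluted scores of incidentally matched genes (e.g. `G020`, 0.17).

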