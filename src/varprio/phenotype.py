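"""Phenotype ontology handling and phenotype-driven gene scoring.

The patient phenome is the union of clinician-curated HPO terms and
terms extracted from the clinical record by NLP (consumed here as a
ready term list), expanded by one degree up the ontology (direct
parents).  Each term ``h`` is weighted inversely to the number of
disease genes annotated to it,

    weight(h) = 1 / |genes(h)|,

so specific findings count more than common, unspecific ones.  A gene's
sum score is the sum of the weights of the phenome terms annotated to
it; genes are ranked by this score and the scores normalized by the
cohort-wide maximum for comparison across cases.
"""

from __future__ import annotations

import csv
import graphlib
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Tuple

logger = logging.getLogger(__name__)

CURATED, NLP, EXPANDED = "curated", "nlp", "expanded"


@dataclass
class HpoTerm:
    """A phenotype-ontology term with its direct DAG neighbours."""

    id: str
    name: str = ""
    parents: set = field(default_factory=set)
    children: set = field(default_factory=set)


class Ontology:
    """An acyclic phenotype ontology: a dict of terms with consistent links."""

    def __init__(self, terms: Iterable[HpoTerm] = ()):
        self.terms: Dict[str, HpoTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise ValueError(f"duplicate term id {t.id}")
            self.terms[t.id] = t
        self._link_and_validate()

    def _link_and_validate(self) -> None:
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise ValueError(
                        f"term {t.id} references undefined parent {p}"
                    )
                self.terms[p].children.add(t.id)
        sorter = graphlib.TopologicalSorter(
            {tid: t.parents for tid, t in self.terms.items()}
        )
        try:
            sorter.prepare()
        except graphlib.CycleError as exc:
            cycle = exc.args[1] if len(exc.args) > 1 else "?"
            raise ValueError(f"ontology contains a cycle: {cycle}") from exc

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> HpoTerm:
        return self.terms[term_id]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[HpoTerm]:
        return iter(self.terms.values())

    def parents_of(self, term_id: str) -> set:
        return set(self.terms[term_id].parents)


def load_ontology(path) -> Ontology:
    """Load an ontology from the simplified TSV dialect.

    Columns: ``term_id``, ``name``, ``parent_ids`` (pipe-separated; empty
    for roots).  Header line required.  Dangling parents and cycles are
    hard errors.
    """
    terms: List[HpoTerm] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return Ontology()
        required = {"term_id", "name", "parent_ids"}
        if not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: ontology TSV must have columns {sorted(required)}"
            )
        for row in reader:
            parents = {p for p in (row["parent_ids"] or "").split("|") if p}
            terms.append(HpoTerm(row["term_id"], row["name"], parents))
    return Ontology(terms)


class PhenotypeAnnotationMap:
    """Bidirectional term <-> gene annotation map (HPO-export style)."""

    def __init__(self, pairs: Iterable[Tuple[str, str]]):
        t2g: Dict[str, set] = {}
        g2t: Dict[str, set] = {}
        for term, gene in pairs:
            if not gene:
                raise ValueError(f"empty gene symbol for term {term}")
            t2g.setdefault(term, set()).add(gene)
            g2t.setdefault(gene, set()).add(term)
        self.term_to_genes: Dict[str, FrozenSet[str]] = {
            t: frozenset(g) for t, g in t2g.items()
        }
        self.gene_to_terms: Dict[str, FrozenSet[str]] = {
            g: frozenset(t) for g, t in g2t.items()
        }

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeAnnotationMap":
        """Read a two-column TSV (term_id, gene_symbol), header required."""
        pairs = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                return cls([])
            if not {"term_id", "gene_symbol"}.issubset(reader.fieldnames):
                raise ValueError(
                    f"{path}: annotation TSV needs term_id and gene_symbol columns"
                )
            for row in reader:
                pairs.append((row["term_id"], row["gene_symbol"]))
        return cls(pairs)

    @property
    def genes(self) -> Iterable[str]:
        return self.gene_to_terms.keys()


class PatientPhenome:
    """The patient's phenotype term set with per-term provenance."""

    def __init__(self, terms: Optional[Mapping[str, str]] = None):
        # term id -> provenance in {curated, nlp, expanded}
        self.terms: Dict[str, str] = dict(terms or {})

    @property
    def term_ids(self) -> set:
        return set(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)


def assemble_phenome(
    curated: Iterable[str], nlp: Iterable[str], ontology: Ontology
) -> PatientPhenome:
    """Merge curated and NLP term lists and expand one degree upward.

    Duplicates are removed with curated provenance winning; term ids not
    in the ontology are dropped with a warning.
    """
    phenome = PatientPhenome()
    for provenance, ids in ((CURATED, curated), (NLP, nlp)):
        for tid in ids:
            if tid not in ontology:
                logger.warning("dropping unknown phenotype term %s", tid)
                continue
            phenome.terms.setdefault(tid, provenance)
    return expand_phenome(phenome, ontology)


def expand_phenome(phenome: PatientPhenome, ontology: Ontology) -> PatientPhenome:
    """Add, with provenance ``expanded``, the direct parents of each term.

    Only terms at graph distance 1 (parents) are added; grandparents are
    not reached unless already present as input terms.
    """
    out = PatientPhenome(phenome.terms)
    for tid in list(phenome.terms):
        for parent in ontology.parents_of(tid):
            out.terms.setdefault(parent, EXPANDED)
    return out


def term_weight(
    term: str, annotations: PhenotypeAnnotationMap
) -> Optional[float]:
    """Inverse of the number of genes annotated to ``term``.

    Returns None (the "no-weight" sentinel) for terms with no associated
    gene; such terms are excluded from gene scoring.
    """
    genes = annotations.term_to_genes.get(term, frozenset())
    if not genes:
        return None
    return 1.0 / len(genes)


@dataclass
class GeneScore:
    """Per-gene phenotype-match score."""

    gene: str
    sum_score: float
    normalized_score: float = 0.0
    matched_terms: FrozenSet[str] = frozenset()


def gene_sum_score(
    gene: str, phenome: PatientPhenome, annotations: PhenotypeAnnotationMap
) -> GeneScore:
    """Sum of term weights over phenome terms annotated to ``gene``."""
    annotated = annotations.gene_to_terms.get(gene, frozenset())
    matched = []
    total = 0.0
    for tid in phenome.term_ids & annotated:
        w = term_weight(tid, annotations)
        if w is None:
            continue
        matched.append(tid)
        total += w
    return GeneScore(gene, total, matched_terms=frozenset(matched))


def rank_genes(
    phenome: PatientPhenome, annotations: PhenotypeAnnotationMap
) -> List[GeneScore]:
    """Score every annotated gene; descending score, ties lexicographic.

    ``normalized_score`` is sum_score divided by the maximum sum score
    (all zero when no gene scores positively).
    """
    scores = [gene_sum_score(g, phenome, annotations) for g in annotations.genes]
    scores.sort(key=lambda s: (-s.sum_score, s.gene))
    top = scores[0].sum_score if scores else 0.0
    if top > 0:
        for s in scores:
            s.normalized_score = s.sum_score / top
    return scores
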