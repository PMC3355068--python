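"""Annotation corpora: GAF parsing, evidence filtering, author provenance,
and per-genome term-frequency (information-content) tables.

Term probabilities are estimated separately for each genome, so that a
term's information content reflects how often that species' curated
corpus uses it, not the database-wide frequency.  Counting is gene-level:
a gene annotated k times with one term contributes once, and every
annotated gene propagates to its namespace root, so p(root) = 1 exactly.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import GafParseError
from .ontology import Ontology

log = logging.getLogger(__name__)

#: experimental evidence codes (EXP and children)
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IEP", "IGI", "IMP", "IPI"})
#: uncurated electronic annotation
UNCURATED_CODES = frozenset({"IEA"})

EVIDENCE_CLASSES = ("experimental", "curated", "uncurated")

_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_author(name: str) -> str:
    """Case-fold, strip punctuation and collapse whitespace."""
    return _WS.sub(" ", _PUNCT.sub("", name.casefold())).strip()


@dataclass(frozen=True)
class AnnotationRecord:
    """A single gene-to-term annotation with its provenance."""

    gene: str
    genome: str
    term: str
    evidence: str
    reference: str
    authors: frozenset[str] = frozenset()


@dataclass
class GeneAnnotationSet:
    """All annotation records of one gene, with per-namespace term views."""

    gene: str
    genome: str
    records: list[AnnotationRecord] = field(default_factory=list)

    def terms_by_namespace(self, o: Ontology) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(o.namespace_of[r.term], set()).add(r.term)
        return {ns: frozenset(ts) for ns, ts in out.items()}

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(r.term for r in self.records)

    @property
    def references(self) -> frozenset[str]:
        return frozenset(r.reference for r in self.records)

    @property
    def authors(self) -> frozenset[str]:
        return frozenset(a for r in self.records for a in r.authors)


@dataclass
class TermFrequencyTable:
    """Per-genome, per-namespace annotation probabilities.

    ``count[c]`` is the number of annotated genes whose propagated
    annotation set contains ``c``; ``total`` the number of genes with at
    least one term in the namespace; ``p(c) = count[c]/total``.
    """

    genome: str
    namespace: str
    count: dict[str, int]
    total: int

    def p(self, term: str) -> float:
        """Probability of the term; raises KeyError if never annotated."""
        return self.count[term] / self.total

    def p_or_min(self, term: str) -> float:
        """Probability with fallback to the smallest representable
        frequency (1/total) for terms absent from this corpus."""
        c = self.count.get(term)
        return (c if c else 1) / self.total

    def ic(self, term: str) -> float:
        """Information content −ln p(term), in nats (fallback as above)."""
        return -math.log(self.p_or_min(term)) + 0.0  # avoid negative zero

    def __contains__(self, term: str) -> bool:
        return term in self.count


# ---------------------------------------------------------------------------
# GAF parsing

_GAF_MIN_COLS = 15  # GAF 2.0/2.1/2.2 have 17 columns; 15 covers all we read


def parse_gaf(path, o: Ontology, genome: str | None = None) -> list[AnnotationRecord]:
    """Parse a GAF 2.x file into annotation records.

    NOT-qualified lines are dropped, terms are mapped through ``alt_id``,
    and lines whose term is absent from the ontology (or obsolete) are
    dropped with a logged count.  The genome defaults to the taxon column.

    Raises
    ------
    GafParseError
        On lines with too few tab-separated columns (names the line).
    """
    records: list[AnnotationRecord] = []
    dropped_terms = 0
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < _GAF_MIN_COLS:
            raise GafParseError(
                f"line {lineno}: expected >= {_GAF_MIN_COLS} columns, got {len(cols)}"
            )
        qualifier, term, reference, evidence = cols[3], cols[4], cols[5], cols[6]
        if "NOT" in qualifier.split("|"):
            continue
        try:
            term = o.resolve(term)
        except KeyError:
            dropped_terms += 1
            continue
        taxon = cols[12].split("|")[0].removeprefix("taxon:")
        records.append(
            AnnotationRecord(
                gene=cols[1],
                genome=genome if genome is not None else taxon,
                term=term,
                evidence=evidence,
                reference=reference,
            )
        )
    if dropped_terms:
        log.info("parse_gaf: dropped %d records with unknown/obsolete terms", dropped_terms)
    return records


def filter_evidence(
    records: Iterable[AnnotationRecord], evidence_class: str
) -> list[AnnotationRecord]:
    """Keep records of one evidence class.

    ``experimental`` keeps exactly EXP/IDA/IEP/IGI/IMP/IPI, ``uncurated``
    keeps exactly IEA, ``curated`` keeps the complement.
    """
    if evidence_class not in EVIDENCE_CLASSES:
        raise ValueError(
            f"unknown evidence class {evidence_class!r}; expected one of {EVIDENCE_CLASSES}"
        )
    if evidence_class == "experimental":
        keep = lambda e: e in EXPERIMENTAL_CODES  # noqa: E731
    elif evidence_class == "uncurated":
        keep = lambda e: e in UNCURATED_CODES  # noqa: E731
    else:
        keep = lambda e: e not in EXPERIMENTAL_CODES and e not in UNCURATED_CODES  # noqa: E731
    return [r for r in records if keep(r.evidence)]


def read_author_map(path) -> dict[str, frozenset[str]]:
    """Read a reference -> authors TSV (semicolon-joined author names)."""
    out: dict[str, frozenset[str]] = {}
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        ref, _, authors = line.partition("\t")
        out[ref] = frozenset(
            normalize_author(a) for a in authors.split(";") if a.strip()
        )
    return out


def attach_authors(
    records: Sequence[AnnotationRecord],
    author_map: Mapping[str, frozenset[str]],
) -> list[AnnotationRecord]:
    """Attach each record's (normalized) author set from its reference.

    Unmapped references get the empty set and are counted in the log.
    """
    unmapped = 0
    out = []
    for r in records:
        authors = author_map.get(r.reference)
        if authors is None:
            unmapped += 1
            authors = frozenset()
        out.append(replace(r, authors=authors))
    if unmapped:
        log.info("attach_authors: %d records had unmapped references", unmapped)
    return out


# ---------------------------------------------------------------------------
# Gene grouping and term frequencies

def group_by_gene(records: Iterable[AnnotationRecord]) -> dict[tuple[str, str], GeneAnnotationSet]:
    """Group records into per-gene annotation sets keyed by (genome, gene)."""
    out: dict[tuple[str, str], GeneAnnotationSet] = {}
    for r in records:
        key = (r.genome, r.gene)
        if key not in out:
            out[key] = GeneAnnotationSet(gene=r.gene, genome=r.genome)
        out[key].records.append(r)
    return out


def term_frequencies(
    genes: Iterable[GeneAnnotationSet], o: Ontology, genome: str
) -> dict[str, TermFrequencyTable]:
    """Per-genome term probabilities with ancestor propagation.

    Returns one table per namespace in which at least one gene of the
    genome is annotated; namespaces with an empty corpus are absent.
    """
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for g in genes:
        if g.genome != genome:
            raise ValueError(f"gene {g.gene} belongs to genome {g.genome}, not {genome}")
        for ns, terms in g.terms_by_namespace(o).items():
            propagated: set[str] = set()
            for t in terms:
                propagated |= o.ancestors(t)
            totals[ns] = totals.get(ns, 0) + 1
            ns_counts = counts.setdefault(ns, {})
            for t in propagated:
                ns_counts[t] = ns_counts.get(t, 0) + 1
    return {
        ns: TermFrequencyTable(genome=genome, namespace=ns, count=counts[ns], total=totals[ns])
        for ns in totals
    }
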