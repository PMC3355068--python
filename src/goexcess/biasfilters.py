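"""Authorship-bias partitioning and pair-level provenance filtering.

Two homologous genes annotated by the same article — or by articles
sharing an author — look more functionally similar than their biology
warrants, because one curation effort tends to assign the same terms to
related genes.  Pairs are classified by provenance (same article, shared
author, disjoint authors), and the main analysis restricts each pair's
annotations to the provenance-independent subsets before any similarity
is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .annotations import AnnotationRecord

log = logging.getLogger(__name__)

PROVENANCE_CLASSES = ("same_article", "shared_author", "disjoint_authors")
PROVENANCE_MODES = ("all",) + PROVENANCE_CLASSES


def classify_provenance(
    recs_i: Sequence[AnnotationRecord],
    recs_j: Sequence[AnnotationRecord],
    strict: bool = False,
) -> str | None:
    """Classify a gene pair's annotation provenance.

    ``same_article`` if any reference identifier is shared, else
    ``shared_author`` if any normalized author name is shared, else
    ``disjoint_authors``.  In ``strict`` mode, pairs where both sides
    lack author data (so author sharing cannot be ruled out) return None
    and are excluded by callers.
    """
    if not recs_i or not recs_j:
        raise ValueError("classify_provenance requires non-empty record lists")
    refs_i = {r.reference for r in recs_i}
    refs_j = {r.reference for r in recs_j}
    if refs_i & refs_j:
        return "same_article"
    authors_i = {a for r in recs_i for a in r.authors}
    authors_j = {a for r in recs_j for a in r.authors}
    if authors_i & authors_j:
        return "shared_author"
    if strict and (not authors_i or not authors_j):
        return None
    return "disjoint_authors"


def restrict_to_independent(
    recs_i: Sequence[AnnotationRecord],
    recs_j: Sequence[AnnotationRecord],
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Drop every annotation whose reference or authors intersect the
    *other* gene's pre-filter references/authors, symmetrically.

    Both sides are filtered against the partner's full unfiltered
    provenance, which makes the operation order-independent and
    idempotent.  Either side emptying means the pair has no independent
    annotations and is excluded by callers.
    """
    refs_i = {r.reference for r in recs_i}
    refs_j = {r.reference for r in recs_j}
    authors_i = {a for r in recs_i for a in r.authors}
    authors_j = {a for r in recs_j for a in r.authors}

    kept_i = [
        r for r in recs_i
        if r.reference not in refs_j and not (set(r.authors) & authors_j)
    ]
    kept_j = [
        r for r in recs_j
        if r.reference not in refs_i and not (set(r.authors) & authors_i)
    ]
    return kept_i, kept_j


@dataclass
class ProvenanceFilterResult:
    """Outcome of applying a provenance mode to one pair."""

    recs_i: list[AnnotationRecord]
    recs_j: list[AnnotationRecord]
    kept: bool
    provenance: str | None


def apply_provenance_mode(
    recs_i: Sequence[AnnotationRecord],
    recs_j: Sequence[AnnotationRecord],
    mode: str = "disjoint_authors",
    strict: bool = False,
) -> ProvenanceFilterResult:
    """Apply a provenance mode to one pair's records.

    ``all`` keeps everything; ``same_article``/``shared_author`` keep
    only pairs of that class, with records untouched; the main-analysis
    ``disjoint_authors`` mode restricts annotations to independent
    subsets (dropping the pair when either side empties).
    """
    if mode not in PROVENANCE_MODES:
        raise ValueError(f"unknown provenance mode {mode!r}; expected one of {PROVENANCE_MODES}")
    cls = classify_provenance(recs_i, recs_j, strict=strict)
    if cls is None:
        return ProvenanceFilterResult(list(recs_i), list(recs_j), kept=False, provenance=None)
    if mode == "all":
        return ProvenanceFilterResult(list(recs_i), list(recs_j), kept=True, provenance=cls)
    if mode in ("same_article", "shared_author"):
        return ProvenanceFilterResult(
            list(recs_i), list(recs_j), kept=(cls == mode), provenance=cls
        )
    kept_i, kept_j = restrict_to_independent(recs_i, recs_j)
    return ProvenanceFilterResult(
        kept_i, kept_j, kept=bool(kept_i) and bool(kept_j), provenance=cls
    )
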