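"""Shared fixtures: the 5-term worked DAG and its 10-gene corpus."""

from __future__ import annotations

import pytest

from goexcess.annotations import (
    AnnotationRecord,
    GeneAnnotationSet,
    term_frequencies,
)
from goexcess.ontology import build_ontology
from goexcess.similarity import TermSimilarityContext

NS = "biological_process"

#: 5-term DAG: C below A and B, D below B, A and B below root R
DAG1_EDGES = [
    ("A", "R", "is_a"),
    ("B", "R", "is_a"),
    ("C", "A", "is_a"),
    ("C", "B", "is_a"),
    ("D", "B", "is_a"),
]
DAG1_PARENTS = {"R": set(), "A": {"R"}, "B": {"R"}, "C": {"A", "B"}, "D": {"B"}}

#: direct single-term annotations of the 10-gene corpus: A x2, B x4, C x1, D x3
DAG1_CORPUS_TERMS = ["A", "A", "B", "B", "B", "B", "C", "D", "D", "D"]


def make_genes(genome: str, term_lists: list[list[str]]) -> list[GeneAnnotationSet]:
    """Build annotated genes with synthetic provenance-free records."""
    genes = []
    for i, terms in enumerate(term_lists):
        gs = GeneAnnotationSet(gene=f"{genome}_g{i}", genome=genome)
        gs.records = [
            AnnotationRecord(
                gene=gs.gene, genome=genome, term=t, evidence="IDA",
                reference=f"PMID:{genome}{i}",
            )
            for t in terms
        ]
        genes.append(gs)
    return genes


@pytest.fixture(scope="session")
def dag1():
    return build_ontology({t: NS for t in "RABCD"}, DAG1_EDGES)


@pytest.fixture(scope="session")
def dag1_genes(dag1):
    return make_genes("sp1", [[t] for t in DAG1_CORPUS_TERMS])


@pytest.fixture(scope="session")
def dag1_freq(dag1, dag1_genes):
    return term_frequencies(dag1_genes, dag1, "sp1")[NS]


@pytest.fixture()
def dag1_ctx(dag1, dag1_freq):
    """Both genomes backed by the same 10-gene corpus."""
    return TermSimilarityContext(ontology=dag1, freq_a=dag1_freq, freq_b=dag1_freq)
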