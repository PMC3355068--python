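"""Semantic similarity measures between ontology terms and between genes.

Term-level measures are information-theoretic (Resnik, Lin) with the twist
that term probabilities are per-genome: Lin's similarity between terms
c_i, c_j annotated in genomes g_i, g_j uses each genome's own frequency
table for the respective annotation term, and a symmetrized probability of
the most-informative common ancestor (MICA).  Gene-level measures pair up
the two genes' term sets: max / average over the full term-pair matrix,
two best-match-average (Schlicker-style) weightings — per annotation and
per gene product — and the graph-only Maryland-bridge overlap of
root-stripped propagated term sets.

All information contents are natural-log (nats); Lin, Maryland-bridge and
Schlicker-of-Lin scores live in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotations import GeneAnnotationSet, TermFrequencyTable
from .errors import UndefinedICError
from .ontology import Ontology

log = logging.getLogger(__name__)

TERM_MEASURES = ("resnik", "lin")
PAIRING_MODES = (
    "max", "avg", "schlicker_annotation", "schlicker_geneproduct", "maryland_bridge",
)


@dataclass
class MeasureConfig:
    """Which similarity measure the analysis uses.

    The default — the per-annotation-weighted best-match average of Lin's
    genome-aware term similarity — is the pipeline's headline measure; the
    alternatives are kept for robustness comparisons.
    """

    term_measure: str = "lin"
    pairing: str = "schlicker_annotation"
    mica_probability: str = "mean"  # mean | first | second
    combined_weighting: str = "annotation_count"  # annotation_count | unweighted

    def validate(self) -> "MeasureConfig":
        if self.term_measure not in TERM_MEASURES:
            raise ValueError(f"term_measure must be one of {TERM_MEASURES}")
        if self.pairing not in PAIRING_MODES:
            raise ValueError(f"pairing must be one of {PAIRING_MODES}")
        if self.mica_probability not in ("mean", "first", "second"):
            raise ValueError("mica_probability must be mean|first|second")
        if self.combined_weighting not in ("annotation_count", "unweighted"):
            raise ValueError("combined_weighting must be annotation_count|unweighted")
        return self


@dataclass
class TermSimilarityContext:
    """Ontology plus the two genomes' frequency tables for one namespace.

    The context memoises term-pair similarities, which dominates runtime
    when many gene pairs from the same genome pair are scored.
    """

    ontology: Ontology
    freq_a: TermFrequencyTable
    freq_b: TermFrequencyTable
    mica_probability: str = "mean"
    _pair_cache: dict[tuple[str, str, str], float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.freq_a.namespace != self.freq_b.namespace:
            raise ValueError(
                f"frequency tables span namespaces {self.freq_a.namespace} "
                f"and {self.freq_b.namespace}"
            )
        self.namespace = self.freq_a.namespace

    def swapped(self) -> "TermSimilarityContext":
        return TermSimilarityContext(
            ontology=self.ontology, freq_a=self.freq_b, freq_b=self.freq_a,
            mica_probability={"first": "second", "second": "first"}.get(
                self.mica_probability, self.mica_probability),
        )

    # -- probabilities ----------------------------------------------------
    def p_bar(self, term: str) -> float:
        """Cross-genome probability of a term.

        ``mean`` (default) averages the two per-genome probabilities, a
        term absent from one corpus contributing that table's smallest
        representable frequency; ``first``/``second`` use a single table.
        """
        if self.mica_probability == "first":
            return self.freq_a.p_or_min(term)
        if self.mica_probability == "second":
            return self.freq_b.p_or_min(term)
        return 0.5 * (self.freq_a.p_or_min(term) + self.freq_b.p_or_min(term))

    def _check_present(self, c_i: str, c_j: str) -> None:
        if c_i not in self.freq_a:
            raise UndefinedICError(
                f"term {c_i} absent from genome {self.freq_a.genome}'s corpus"
            )
        if c_j not in self.freq_b:
            raise UndefinedICError(
                f"term {c_j} absent from genome {self.freq_b.genome}'s corpus"
            )

    # -- term measures ----------------------------------------------------
    def mica(self, c_i: str, c_j: str) -> tuple[str, float]:
        """Most-informative common ancestor and its IC in nats.

        Ties on IC are broken toward the lexicographically smallest term
        (the score is identical for all tied ancestors).
        """
        common = self.ontology.common_ancestors(c_i, c_j)
        if not common:
            raise ValueError(f"terms {c_i}, {c_j} share no ancestor (cross-namespace?)")
        best, best_ic = None, -1.0
        for a in sorted(common):
            ic = -math.log(self.p_bar(a))
            if ic > best_ic + 1e-15:
                best, best_ic = a, ic
        return best, max(best_ic, 0.0)

    def sim_resnik(self, c_i: str, c_j: str) -> float:
        """IC of the MICA under the cross-genome probability; >= 0 nats."""
        self._check_present(c_i, c_j)
        return self.mica(c_i, c_j)[1]

    def sim_lin(self, c_i: str, c_j: str) -> float:
        """2·IC(MICA) / (IC_{g_i}(c_i) + IC_{g_j}(c_j)), clamped to [0, 1].

        Both annotation ICs zero (both terms carried by every annotated
        gene, e.g. the root) gives 0: such terms relate genes only through
        near-root vocabulary.
        """
        self._check_present(c_i, c_j)
        denom = self.freq_a.ic(c_i) + self.freq_b.ic(c_j)
        if denom <= 0.0:
            return 0.0
        return min(1.0, max(0.0, 2.0 * self.mica(c_i, c_j)[1] / denom))

    def sim_term(self, c_i: str, c_j: str, term_measure: str) -> float:
        key = (c_i, c_j, term_measure)
        v = self._pair_cache.get(key)
        if v is None:
            v = self.sim_lin(c_i, c_j) if term_measure == "lin" else self.sim_resnik(c_i, c_j)
            self._pair_cache[key] = v
        return v


# -- module-level term operations ------------------------------------------

def sim_resnik(c_i: str, c_j: str, ctx: TermSimilarityContext) -> float:
    return ctx.sim_resnik(c_i, c_j)


def sim_lin(c_i: str, c_j: str, ctx: TermSimilarityContext) -> float:
    return ctx.sim_lin(c_i, c_j)


# -- gene-level pairings ----------------------------------------------------

def sim_gene_pairing(
    p_i: Iterable[str],
    p_j: Iterable[str],
    ctx: TermSimilarityContext,
    mode: str = "schlicker_annotation",
    term_measure: str = "lin",
) -> float:
    """Aggregate the |p_i| x |p_j| term-similarity matrix into one score.

    ``max``/``avg`` take the maximum / mean of the matrix.  The two
    best-match averages differ in weighting: ``schlicker_annotation``
    gives each annotation term equal weight,
    (Σ_x max_y s + Σ_y max_x s) / (|p_i| + |p_j|), while
    ``schlicker_geneproduct`` gives each gene product equal weight,
    (mean_x max_y s + mean_y max_x s) / 2.
    """
    p_i, p_j = sorted(set(p_i)), sorted(set(p_j))
    if not p_i or not p_j:
        raise ValueError("gene-level similarity requires non-empty term sets")
    s = [[ctx.sim_term(x, y, term_measure) for y in p_j] for x in p_i]
    if mode == "max":
        return max(max(row) for row in s)
    if mode == "avg":
        return sum(map(sum, s)) / (len(p_i) * len(p_j))
    row_best = [max(row) for row in s]
    col_best = [max(s[i][j] for i in range(len(p_i))) for j in range(len(p_j))]
    if mode == "schlicker_annotation":
        return (sum(row_best) + sum(col_best)) / (len(p_i) + len(p_j))
    if mode == "schlicker_geneproduct":
        return 0.5 * (sum(row_best) / len(p_i) + sum(col_best) / len(p_j))
    raise ValueError(f"unknown pairing mode {mode!r}")


def maryland_bridge(
    p_i: Iterable[str], p_j: Iterable[str], o: Ontology
) -> float | None:
    """Set-overlap similarity of root-stripped propagated term sets.

    MB = |S_i ∩ S_j| / 2 · (1/|S_i| + 1/|S_j|) where S_p is the union of
    ancestor closures of p's terms minus the namespace roots.  Returns
    None (pair skipped, logged) when a gene is annotated with roots only.
    """
    roots = set(o.roots.values())
    s_i: set[str] = set()
    for t in p_i:
        s_i |= o.ancestors(t)
    s_j: set[str] = set()
    for t in p_j:
        s_j |= o.ancestors(t)
    s_i -= roots
    s_j -= roots
    if not s_i or not s_j:
        log.info("maryland_bridge: root-only annotation set, pair skipped")
        return None
    return len(s_i & s_j) / 2.0 * (1.0 / len(s_i) + 1.0 / len(s_j))


class ContextStore:
    """Lazily-built, cached :class:`TermSimilarityContext` per genome pair.

    Sharing contexts across the analysis and the background estimation
    keeps the term-pair memoisation hot for a whole genome pair.
    """

    def __init__(
        self,
        ontology: Ontology,
        freqs: Mapping[str, Mapping[str, TermFrequencyTable]],
        mica_probability: str = "mean",
    ) -> None:
        self.ontology = ontology
        self.freqs = freqs
        self.mica_probability = mica_probability
        self._cache: dict[tuple[str, str], dict[str, TermSimilarityContext]] = {}

    def get(self, genome_a: str, genome_b: str) -> dict[str, TermSimilarityContext]:
        """Contexts for every namespace both genomes have tables for;
        ``freq_a`` belongs to ``genome_a``."""
        key = (genome_a, genome_b)
        ctxs = self._cache.get(key)
        if ctxs is None:
            fa, fb = self.freqs.get(genome_a, {}), self.freqs.get(genome_b, {})
            ctxs = {
                ns: TermSimilarityContext(
                    ontology=self.ontology, freq_a=fa[ns], freq_b=fb[ns],
                    mica_probability=self.mica_probability,
                )
                for ns in sorted(set(fa) & set(fb))
            }
            self._cache[key] = ctxs
        return ctxs


def combined_similarity(
    gene_i: GeneAnnotationSet,
    gene_j: GeneAnnotationSet,
    contexts: Mapping[str, TermSimilarityContext],
    config: MeasureConfig | None = None,
) -> tuple[dict[str, float], float | None]:
    """Per-namespace gene similarity plus the combined cross-namespace score.

    A namespace contributes only when both genes are annotated in it (no
    zero-filling); the combined score is the annotation-count-weighted
    mean of the available per-namespace values (weight = number of
    distinct terms of the pair in that namespace), or the unweighted mean
    under ``combined_weighting='unweighted'``.  Returns ``({}, None)``
    when the genes share no annotated namespace.
    """
    config = (config or MeasureConfig()).validate()
    if not contexts:
        return {}, None
    o = next(iter(contexts.values())).ontology
    terms_i = gene_i.terms_by_namespace(o)
    terms_j = gene_j.terms_by_namespace(o)
    per_ns: dict[str, float] = {}
    weights: dict[str, float] = {}
    for ns in sorted(set(terms_i) & set(terms_j)):
        if ns not in contexts:
            continue
        if config.pairing == "maryland_bridge":
            v = maryland_bridge(terms_i[ns], terms_j[ns], contexts[ns].ontology)
            if v is None:
                continue
        else:
            v = sim_gene_pairing(
                terms_i[ns], terms_j[ns], contexts[ns],
                mode=config.pairing, term_measure=config.term_measure,
            )
        per_ns[ns] = v
        weights[ns] = (
            float(len(terms_i[ns]) + len(terms_j[ns]))
            if config.combined_weighting == "annotation_count" else 1.0
        )
    if not per_ns:
        log.info(
            "combined_similarity: genes %s/%s share no annotated namespace",
            gene_i.gene, gene_j.gene,
        )
        return {}, None
    total_w = sum(weights.values())
    combined = sum(per_ns[ns] * weights[ns] for ns in per_ns) / total_w
    return per_ns, combined
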