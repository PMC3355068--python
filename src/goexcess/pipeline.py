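"""End-to-end analysis: evidence filtering, per-pair authorship
restriction, per-genome information content, similarity, background
normalization and the statistical battery.

The stage order mirrors the confounder controls: (i) authorship bias is
removed per pair before any similarity is computed; (ii) term
probabilities are estimated per genome from the same evidence-filtered
corpus that enters the analysis; (iii) raw similarities are converted to
excess over the (genome pair, subtype) background; (iv) evidence-class
filtering excludes propagated (IEA) annotation unless asked for.
Counts are conserved and logged at every stage: pairs in = pairs
analyzed + pairs dropped per filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotations as ann
from .background import (
    COMBINED,
    BackgroundTable,
    estimate_background,
    excess_similarity,
)
from .biasfilters import PROVENANCE_MODES, apply_provenance_mode
from .errors import PipelineError
from .homology import HomologPair, apply_identity_cutoff, assign_bin, parse_pairs
from .ontology import Ontology, parse_obo
from .similarity import ContextStore, MeasureConfig, combined_similarity
from .stats import (
    BinTestResult,
    StratumSummary,
    correlations,
    global_tests,
    mannwhitney_by_bin,
    summarize_strata,
)

log = logging.getLogger(__name__)


@dataclass
class AnalysisOptions:
    """Knobs of one analysis run (defaults are the main setting)."""

    evidence_class: str = "experimental"
    provenance_mode: str = "disjoint_authors"
    strict_provenance: bool = False
    measure: MeasureConfig = field(default_factory=MeasureConfig)
    identity_cutoff: float = 10.0
    bin_width: float = 10.0
    background_n: int = 10_000
    seed: int = 0

    def validate(self) -> "AnalysisOptions":
        if self.evidence_class not in ann.EVIDENCE_CLASSES:
            raise PipelineError(f"unknown evidence class {self.evidence_class!r}")
        if self.provenance_mode not in PROVENANCE_MODES:
            raise PipelineError(f"unknown provenance mode {self.provenance_mode!r}")
        self.measure.validate()
        return self


@dataclass
class RunConfig:
    """File-based run configuration (mirrors the CLI flags)."""

    obo: str
    gafs: list[str]
    pairs: str
    authors: str | None = None
    out_dir: str = "results"
    options: AnalysisOptions = field(default_factory=AnalysisOptions)


@dataclass
class AnalysisResult:
    """Everything one run computes."""

    pairs: pd.DataFrame
    background: BackgroundTable
    summaries: list[StratumSummary]
    bin_tests: list[BinTestResult]
    global_tests: dict[str, float]
    correlations: dict[str, tuple[float, float]]
    counts: dict[str, int]
    options: AnalysisOptions


def display_subtype(subtype: str, same_species: bool) -> str:
    """Subtype label with the same-/different-species split for paralogs."""
    if subtype == "outparalog":
        return "outparalog_same_species" if same_species else "outparalog_diff_species"
    return subtype


def analyze(
    ontology: Ontology,
    records: Sequence[ann.AnnotationRecord],
    author_map: Mapping[str, frozenset[str]] | None,
    pairs: Sequence[HomologPair],
    options: AnalysisOptions | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs.

    ``records`` is the pooled annotation corpus of all genomes; genes and
    per-genome frequency tables are derived after evidence filtering, so
    information content is computed on exactly the corpus analyzed.
    """
    options = (options or AnalysisOptions()).validate()
    counts: dict[str, int] = {"pairs_in": len(pairs)}

    # stage: evidence filter (control iv)
    records = ann.filter_evidence(records, options.evidence_class)
    # stage: provenance attachment (control i happens per pair below)
    records = ann.attach_authors(records, author_map or {})
    by_gene = ann.group_by_gene(records)
    genes_by_genome: dict[str, dict[str, ann.GeneAnnotationSet]] = {}
    for (genome, gene), gs in by_gene.items():
        genes_by_genome.setdefault(genome, {})[gene] = gs
    counts["annotated_genes"] = len(by_gene)

    # stage: per-genome term frequencies (control ii)
    freqs = {
        genome: ann.term_frequencies(genes.values(), ontology, genome)
        for genome, genes in genes_by_genome.items()
    }
    store = ContextStore(ontology, freqs, options.measure.mica_probability)

    # stage: identity cutoff and annotation availability
    kept = apply_identity_cutoff(pairs, options.identity_cutoff)
    counts["dropped_identity_cutoff"] = len(pairs) - len(kept)
    have_genes = [
        p for p in kept
        if p.gene_a in genes_by_genome.get(p.genome_a, {})
        and p.gene_b in genes_by_genome.get(p.genome_b, {})
    ]
    counts["dropped_unannotated"] = len(kept) - len(have_genes)

    # stage: background estimation (control iii) on the evidence-filtered
    # corpus; random pairs are provenance-agnostic
    bg = estimate_background(
        genes_by_genome, have_genes, store, options.measure,
        n=options.background_n, seed=options.seed,
    )

    # stage: per-pair provenance restriction + similarity + excess
    rows = []
    dropped_prov = dropped_ns = dropped_bg = 0
    for p in have_genes:
        gi = genes_by_genome[p.genome_a][p.gene_a]
        gj = genes_by_genome[p.genome_b][p.gene_b]
        res = apply_provenance_mode(
            gi.records, gj.records, mode=options.provenance_mode,
            strict=options.strict_provenance,
        )
        if not res.kept:
            dropped_prov += 1
            continue
        fi = ann.GeneAnnotationSet(gene=gi.gene, genome=gi.genome, records=res.recs_i)
        fj = ann.GeneAnnotationSet(gene=gj.gene, genome=gj.genome, records=res.recs_j)
        contexts = store.get(p.genome_a, p.genome_b)
        per_ns, combined = combined_similarity(fi, fj, contexts, options.measure)
        if combined is None:
            dropped_ns += 1
            continue
        excess = excess_similarity(p, combined, bg, COMBINED)
        if excess is None:
            dropped_bg += 1
            continue
        b = assign_bin(p.percent_identity, width=options.bin_width,
                       lower=options.identity_cutoff)
        row = {
            "gene_a": p.gene_a, "gene_b": p.gene_b,
            "genome_a": p.genome_a, "genome_b": p.genome_b,
            "subtype": p.subtype,
            "display_subtype": display_subtype(p.subtype, p.same_species),
            "same_species": p.same_species,
            "percent_identity": p.percent_identity,
            "bin": b.label, "bin_lower": b.lower,
            "family": p.family, "divergence_time": p.divergence_time,
            "provenance": res.provenance,
            "similarity": combined, "excess": excess,
        }
        for ns, v in per_ns.items():
            row[f"similarity_{ns}"] = v
            e = excess_similarity(p, v, bg, ns)
            if e is not None:
                row[f"excess_{ns}"] = e
        rows.append(row)
    counts["dropped_provenance"] = dropped_prov
    counts["dropped_no_shared_namespace"] = dropped_ns
    counts["dropped_missing_background"] = dropped_bg
    counts["pairs_analyzed"] = len(rows)
    assert counts["pairs_in"] == (
        counts["pairs_analyzed"] + counts["dropped_identity_cutoff"]
        + counts["dropped_unannotated"] + dropped_prov + dropped_ns + dropped_bg
    ), "stage counts do not conserve the input pair count"

    df = pd.DataFrame(rows)

    # stage: statistics
    if len(df):
        groups: dict = {}
        for row in df.itertuples(index=False):
            b = assign_bin(row.percent_identity, width=options.bin_width,
                           lower=options.identity_cutoff)
            groups.setdefault((row.display_subtype, b), []).append(row.excess)
        summaries = summarize_strata(groups)

        orth = df[df["subtype"].str.startswith("ortholog")]
        para = df[~df["subtype"].str.startswith("ortholog")]

        def by_bin(sub: pd.DataFrame) -> dict:
            out: dict = {}
            for row in sub.itertuples(index=False):
                b = assign_bin(row.percent_identity, width=options.bin_width,
                               lower=options.identity_cutoff)
                out.setdefault(b, []).append(row.excess)
            return out

        bin_tests = mannwhitney_by_bin(by_bin(orth), by_bin(para))
        gtests = global_tests(df)
        corr = correlations(df)
    else:
        summaries, bin_tests, gtests, corr = [], [], {}, {}

    for stage, n in counts.items():
        log.info("pipeline: %s = %d", stage, n)
    return AnalysisResult(
        pairs=df, background=bg, summaries=summaries, bin_tests=bin_tests,
        global_tests=gtests, correlations=corr, counts=counts, options=options,
    )


# ---------------------------------------------------------------------------
# result serialization

def summaries_frame(summaries: Sequence[StratumSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subtype": s.subtype, "bin": s.bin.label if s.bin else "",
             "n": s.n, "mean_excess": s.mean, "ci_low": s.ci_low,
             "ci_high": s.ci_high, "degenerate": s.degenerate}
            for s in summaries
        ],
        columns=["subtype", "bin", "n", "mean_excess", "ci_low", "ci_high", "degenerate"],
    )


def bin_tests_frame(tests: Sequence[BinTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"bin": t.bin.label, "n_orthologs": t.n_orthologs,
             "n_paralogs": t.n_paralogs, "diff_means": t.diff_means,
             "diff_ci_low": t.diff_ci_low, "diff_ci_high": t.diff_ci_high,
             "u_statistic": t.u_statistic, "p_value": t.p_value,
             "p_holm": t.p_holm}
            for t in tests
        ],
        columns=["bin", "n_orthologs", "n_paralogs", "diff_means",
                 "diff_ci_low", "diff_ci_high", "u_statistic", "p_value", "p_holm"],
    )


def write_result(result: AnalysisResult, out_dir) -> dict[str, Path]:
    """Write result tables as TSV plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["pairs"] = out / "pairs_analyzed.tsv"
    result.pairs.to_csv(files["pairs"], sep="\t", index=False)
    files["summaries"] = out / "stratum_summaries.tsv"
    summaries_frame(result.summaries).to_csv(files["summaries"], sep="\t", index=False)
    files["bin_tests"] = out / "bin_tests.tsv"
    bin_tests_frame(result.bin_tests).to_csv(files["bin_tests"], sep="\t", index=False)
    files["background"] = out / "background.tsv"
    result.background.to_tsv(files["background"])
    files["correlations"] = out / "correlations.tsv"
    pd.DataFrame(
        [{"quantity": k, "rho": v[0], "p_value": v[1]}
         for k, v in sorted(result.correlations.items())],
        columns=["quantity", "rho", "p_value"],
    ).to_csv(files["correlations"], sep="\t", index=False)

    manifest = {
        "counts": result.counts,
        "global_tests": result.global_tests,
        "options": _options_dict(result.options),
    }
    files["manifest"] = out / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return files


def _options_dict(options: AnalysisOptions) -> dict:
    d = dataclasses.asdict(options)
    return d


def run(config: RunConfig) -> AnalysisResult:
    """File-based entry point: parse inputs, analyze, write outputs.

    Any stage's validation error aborts with the stage name attached.
    """
    stage = "parse_obo"
    try:
        ontology = parse_obo(config.obo)
        stage = "parse_gaf"
        records: list[ann.AnnotationRecord] = []
        for gaf in config.gafs:
            records.extend(ann.parse_gaf(gaf, ontology))
        stage = "read_author_map"
        author_map = ann.read_author_map(config.authors) if config.authors else {}
        stage = "parse_pairs"
        pairs = parse_pairs(config.pairs)
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    result = analyze(ontology, records, author_map, pairs, config.options)
    write_result(result, config.out_dir)
    return result
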