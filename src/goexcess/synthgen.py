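"""Synthetic ontologies, annotation corpora, author metadata and homolog
pairs with planted effect structure.

The generator emulates the statistical features the analysis depends on:

* a rooted random DAG ontology per namespace (round-tripped through the
  OBO parser so the file path is exercised);
* per-genome annotation corpora whose term-usage distributions differ
  across genomes (a Dirichlet concentration parameter controls how much),
  with a lab/paper authorship process in which genes annotated by the same
  paper — and papers from the same lab — share provenance;
* gene families with an ancestral term set and a subtype-dependent
  functional-divergence process: a family member retains each ancestral
  term with probability sqrt(δ_subtype · exp(−λ·(100−identity)/100)) and
  otherwise replaces it with a random term of similar depth, so a pair of
  members shares an ancestral term with probability δ_eff and divergence
  changes the identity of the annotated function, not its specificity;
* an authorship-bias channel: a same-species family pair can be
  co-annotated by one shared paper that copies one member's terms onto the
  other, inflating similarity exactly as shared-provenance curation does.

δ_1to1 ≥ δ_other ≥ δ_paralog plants the ortholog conjecture; λ = 0 gives
the divergence-independent ("flat") regime, large λ the received-wisdom
decay regime.  All randomness flows from one seed through per-stage
substreams, so output files are byte-identical across reruns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    AnnotationRecord,
    EXPERIMENTAL_CODES,
    GeneAnnotationSet,
    normalize_author,
)
from .errors import GenerationError
from .homology import HomologPair, SUBTYPES
from .ontology import NAMESPACES, Ontology, parse_obo

_CURATED_CODES = ("TAS", "IC", "NAS")
_EXP_CODES = tuple(sorted(EXPERIMENTAL_CODES))


@dataclass
class AuthorshipConfig:
    """Lab/paper process generating annotation provenance."""

    genes_per_paper: int = 4
    papers_per_lab: int = 3
    authors_per_lab: int = 4
    authors_per_paper: int = 2
    #: probability that a same-species family pair is co-annotated by one
    #: shared paper (the authorship-bias channel)
    p_copaper: float = 0.0


@dataclass
class DivergenceConfig:
    """Planted functional-divergence process per homology subtype."""

    delta_1to1: float = 0.9
    delta_other: float = 0.7
    delta_paralog: float = 0.5
    #: identity-dependent decay rate λ; retention ∝ exp(−λ·(100−id)/100)
    decay_rate: float = 0.0
    #: per-subtype percent-identity sampling ranges (substantially
    #: overlapping so identity bins are populated for every subtype)
    identity_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {s: (15.0, 95.0) for s in SUBTYPES}
    )

    def delta(self, subtype: str) -> float:
        return {
            "ortholog_1to1": self.delta_1to1,
            "ortholog_other": self.delta_other,
        }.get(subtype, self.delta_paralog)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic scenario."""

    seed: int = 0
    n_terms: int = 50  # per namespace
    namespaces: tuple[str, ...] = NAMESPACES
    multi_parent_prob: float = 0.2
    n_genomes: int = 2
    genes_per_genome: int = 150  # background (non-family) genes
    concentration: float = 5.0  # Dirichlet concentration of per-genome term usage
    mean_terms_per_gene: float = 3.0  # Poisson with floor 1
    evidence_mix: dict[str, float] = field(
        default_factory=lambda: {"experimental": 1.0}
    )
    pairs_per_subtype: dict[str, int] = field(
        default_factory=lambda: {s: 300 for s in SUBTYPES}
    )
    authorship: AuthorshipConfig = field(default_factory=AuthorshipConfig)
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)

    @property
    def genomes(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_genomes)]


@dataclass
class Scenario:
    """One generated dataset: ontology, corpora, provenance, pairs, truth."""

    config: GeneratorConfig
    ontology: Ontology
    obo_text: str
    genes_by_genome: dict[str, dict[str, GeneAnnotationSet]]
    author_map: dict[str, frozenset[str]]
    pairs: list[HomologPair]
    truth: pd.DataFrame


def _rng(cfg: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# ontology

def generate_ontology(cfg: GeneratorConfig) -> tuple[Ontology, str]:
    """Random rooted DAG per namespace, emitted as OBO text and reparsed.

    Terms attach to one uniformly chosen existing parent, plus a second
    with ``multi_parent_prob`` (as ``part_of``), which yields multiple
    inheritance without cycles.  Returns the parsed ontology and the OBO
    text (the round trip is part of the contract).
    """
    if cfg.n_terms < 1:
        raise GenerationError("n_terms must be >= 1 per namespace")
    rng = _rng(cfg, 0)
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    counter = itertools.count(1)
    for ns in cfg.namespaces:
        ids = [f"GO:{next(counter):07d}" for _ in range(cfg.n_terms)]
        parents: dict[str, list[tuple[str, str]]] = {ids[0]: []}
        for i in range(1, cfg.n_terms):
            t = ids[i]
            first = ids[int(rng.integers(i))]
            parents[t] = [(first, "is_a")]
            if i >= 2 and rng.random() < cfg.multi_parent_prob:
                second = ids[int(rng.integers(i))]
                if second != first:
                    parents[t].append((second, "part_of"))
        for t in ids:
            lines += ["[Term]", f"id: {t}", f"name: {t} ({ns})", f"namespace: {ns}"]
            for p, rel in parents[t]:
                lines.append(f"is_a: {p}" if rel == "is_a" else f"relationship: {rel} {p}")
            lines.append("")
    text = "\n".join(lines)
    import io

    return parse_obo(io.StringIO(text)), text


# ---------------------------------------------------------------------------
# corpora + authorship

class _PaperMill:
    """Assigns papers (with lab-structured author sets) on demand."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.counter = itertools.count(1)
        self.author_map: dict[str, frozenset[str]] = {}

    def new_paper(self, genome: str) -> str:
        a = self.cfg.authorship
        idx = next(self.counter)
        # labs drawn at random from the pool grown so far, so consecutively
        # created papers (e.g. one family's members) rarely share a lab
        n_labs = 1 + (idx - 1) // max(a.papers_per_lab, 1)
        lab = int(self.rng.integers(n_labs))
        lab_authors = [f"{genome} lab{lab} author{k}" for k in range(a.authors_per_lab)]
        k = min(a.authors_per_paper, len(lab_authors))
        chosen = self.rng.choice(len(lab_authors), size=k, replace=False)
        ref = f"PMID:{idx}"
        self.author_map[ref] = frozenset(
            normalize_author(lab_authors[i]) for i in sorted(chosen)
        )
        return ref


def _draw_evidence(cfg: GeneratorConfig, rng: np.random.Generator) -> str:
    classes = sorted(cfg.evidence_mix)
    probs = np.array([cfg.evidence_mix[c] for c in classes], float)
    cls = classes[int(rng.choice(len(classes), p=probs / probs.sum()))]
    if cls == "experimental":
        return _EXP_CODES[int(rng.integers(len(_EXP_CODES)))]
    if cls == "uncurated":
        return "IEA"
    return _CURATED_CODES[int(rng.integers(len(_CURATED_CODES)))]


def _usage_distributions(
    cfg: GeneratorConfig, o: Ontology, rng: np.random.Generator
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Per-genome term-usage distributions over non-root terms.

    Base usage is uniform; each genome draws Dirichlet(concentration ×
    base), so large concentration means near-identical frequencies across
    genomes and small concentration strong per-genome skew.
    """
    roots = set(o.roots.values())
    vocab = sorted(t for t in o.terms if t not in roots)
    if not vocab:
        raise GenerationError("ontology has no non-root terms to annotate with")
    alpha = np.full(len(vocab), cfg.concentration)
    return vocab, {g: rng.dirichlet(alpha) for g in cfg.genomes}


def _n_terms_for_gene(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    return 1 + int(rng.poisson(max(cfg.mean_terms_per_gene - 1.0, 0.0)))


def _records_for_gene(
    cfg: GeneratorConfig,
    gene: str,
    genome: str,
    terms: Sequence[str],
    ref: str,
    rng: np.random.Generator,
) -> list[AnnotationRecord]:
    return [
        AnnotationRecord(
            gene=gene, genome=genome, term=t, evidence=_draw_evidence(cfg, rng),
            reference=ref,
        )
        for t in sorted(terms)
    ]


def generate_corpora(
    cfg: GeneratorConfig, o: Ontology
) -> tuple[dict[str, dict[str, GeneAnnotationSet]], dict[str, frozenset[str]], _PaperMill]:
    """Background annotation corpora plus the author metadata table.

    Every gene's terms are referenced to its "home paper"; consecutive
    genes share papers (``genes_per_paper``) and consecutive papers share
    labs, which induces same-article and shared-author provenance among
    within-genome gene neighbourhoods.
    """
    rng = _rng(cfg, 1)
    vocab, usage = _usage_distributions(cfg, o, rng)
    mill = _PaperMill(cfg, rng)
    genes_by_genome: dict[str, dict[str, GeneAnnotationSet]] = {}
    for genome in cfg.genomes:
        genes: dict[str, GeneAnnotationSet] = {}
        paper, used_in_paper = None, 0
        for i in range(cfg.genes_per_genome):
            if paper is None or used_in_paper >= cfg.authorship.genes_per_paper:
                paper, used_in_paper = mill.new_paper(genome), 0
            used_in_paper += 1
            gene = f"{genome}_g{i + 1:04d}"
            k = min(_n_terms_for_gene(cfg, rng), len(vocab))
            idx = rng.choice(len(vocab), size=k, replace=False, p=usage[genome])
            terms = [vocab[j] for j in sorted(idx)]
            gs = GeneAnnotationSet(gene=gene, genome=genome)
            gs.records = _records_for_gene(cfg, gene, genome, terms, paper, rng)
            genes[gene] = gs
        genes_by_genome[genome] = genes
    return genes_by_genome, dict(mill.author_map), mill


# ---------------------------------------------------------------------------
# families

def _family_plan(cfg: GeneratorConfig) -> list[tuple[str, tuple]]:
    """Deterministic family layout meeting the per-subtype pair counts.

    Each family yields pairs of a single subtype:
    one-to-one families place one member per genome (all pairwise edges
    are 1:1 — with three or more genomes this creates complete ortholog
    triplets); ``ortholog_other`` families place one member in one genome
    and two in another; ``inparalog`` families two members in one genome;
    ``outparalog`` families alternate within- and between-species layouts.
    """
    genomes = cfg.genomes
    cross = list(itertools.combinations(genomes, 2))
    plan: list[tuple[str, tuple]] = []

    want = cfg.pairs_per_subtype
    per_family_11 = max(len(cross), 1)
    n11 = math.ceil(want.get("ortholog_1to1", 0) / per_family_11)
    for i in range(n11):
        plan.append(("ortholog_1to1", tuple(genomes)))
    nother = math.ceil(want.get("ortholog_other", 0) / 2)
    for i in range(nother):
        a, b = cross[i % len(cross)] if cross else (genomes[0], genomes[0])
        if not cross:
            raise GenerationError("ortholog pairs need at least two genomes")
        plan.append(("ortholog_other", (a, b)))
    for i in range(want.get("inparalog", 0)):
        plan.append(("inparalog", (genomes[i % len(genomes)],)))
    for i in range(want.get("outparalog", 0)):
        if cross and i % 2 == 0:
            plan.append(("outparalog", cross[(i // 2) % len(cross)]))
        else:
            plan.append(("outparalog", (genomes[i % len(genomes)],)))
    return plan


def _diverged_terms(
    ancestral: Sequence[str],
    retention: float,
    o: Ontology,
    rng: np.random.Generator,
) -> list[str]:
    """Retain each ancestral term with the given probability, otherwise
    replace it with a random same-namespace term of similar depth."""
    out = []
    for t in ancestral:
        if rng.random() < retention:
            out.append(t)
            continue
        ns = o.namespace_of[t]
        candidates = [
            c for c in o.terms_at_depth(ns, o.depth(t), tolerance=1)
            if c != t and not o.is_root(c)
        ]
        out.append(candidates[int(rng.integers(len(candidates)))] if candidates else t)
    return sorted(set(out))


def generate_families(
    cfg: GeneratorConfig,
    o: Ontology,
    genes_by_genome: dict[str, dict[str, GeneAnnotationSet]],
    mill: _PaperMill,
) -> tuple[list[HomologPair], pd.DataFrame]:
    """Gene families with the planted divergence process.

    Family members are appended to the corpora as new genes (with their
    own home papers).  With probability ``p_copaper`` a same-species
    family pair is additionally co-annotated by one shared paper that
    copies the first member's term set onto both genes — the planted
    authorship bias.  Returns the labeled pairs and the planted-truth
    table.
    """
    rng = _rng(cfg, 2)
    roots = set(o.roots.values())
    vocab = sorted(t for t in o.terms if t not in roots)
    div = cfg.divergence
    next_idx = {g: len(genes_by_genome[g]) + 1 for g in cfg.genomes}

    def new_member(genome: str, terms: Sequence[str]) -> GeneAnnotationSet:
        gene = f"{genome}_g{next_idx[genome]:04d}"
        next_idx[genome] += 1
        gs = GeneAnnotationSet(gene=gene, genome=genome)
        gs.records = _records_for_gene(cfg, gene, genome, terms, mill.new_paper(genome), rng)
        genes_by_genome[genome][gene] = gs
        return gs

    pairs: list[HomologPair] = []
    truth_rows = []
    emitted = {s: 0 for s in SUBTYPES}
    for fam_no, (subtype, layout) in enumerate(_family_plan(cfg), start=1):
        fam = f"fam{fam_no:05d}"
        lo, hi = div.identity_ranges[subtype]
        identity = float(rng.uniform(lo, hi))
        delta_eff = div.delta(subtype) * math.exp(-div.decay_rate * (100.0 - identity) / 100.0)
        retention = math.sqrt(max(min(delta_eff, 1.0), 0.0))
        k = min(_n_terms_for_gene(cfg, rng), len(vocab))
        ancestral = [vocab[j] for j in sorted(rng.choice(len(vocab), size=k, replace=False))]

        if subtype == "ortholog_1to1":
            members = [(g, new_member(g, _diverged_terms(ancestral, retention, o, rng)))
                       for g in layout]
            combos = list(itertools.combinations(members, 2))
        elif subtype == "ortholog_other":
            a, b = layout
            ma = (a, new_member(a, _diverged_terms(ancestral, retention, o, rng)))
            mb1 = (b, new_member(b, _diverged_terms(ancestral, retention, o, rng)))
            mb2 = (b, new_member(b, _diverged_terms(ancestral, retention, o, rng)))
            combos = [(ma, mb1), (ma, mb2)]
            members = [ma, mb1, mb2]
        else:
            if len(layout) == 1:
                g = layout[0]
                members = [(g, new_member(g, _diverged_terms(ancestral, retention, o, rng)))
                           for _ in range(2)]
            else:
                members = [(g, new_member(g, _diverged_terms(ancestral, retention, o, rng)))
                           for g in layout]
            combos = [(members[0], members[1])]

        # authorship-bias channel: shared-paper co-annotation of
        # same-species members
        for (ga, ma), (gb, mb) in itertools.combinations(members, 2):
            if ga != gb or rng.random() >= cfg.authorship.p_copaper:
                continue
            shared = mill.new_paper(ga)
            source_terms = sorted(ma.terms)
            ma.records += _records_for_gene(cfg, ma.gene, ga, source_terms, shared, rng)
            mb.records += _records_for_gene(cfg, mb.gene, gb, source_terms, shared, rng)

        for (ga, ma), (gb, mb) in combos:
            if emitted[subtype] >= cfg.pairs_per_subtype.get(subtype, 0):
                break
            pairs.append(
                HomologPair(
                    gene_a=ma.gene, gene_b=mb.gene, genome_a=ga, genome_b=gb,
                    subtype=subtype, percent_identity=identity, family=fam,
                ).validate()
            )
            emitted[subtype] += 1
        truth_rows.append(
            {"family": fam, "subtype": subtype, "identity": identity,
             "delta": div.delta(subtype), "delta_effective": delta_eff,
             "n_ancestral_terms": len(ancestral)}
        )
    truth = pd.DataFrame(truth_rows)
    return pairs, truth


# ---------------------------------------------------------------------------
# scenario assembly and file output

def generate_scenario(cfg: GeneratorConfig) -> Scenario:
    """Generate a complete scenario (ontology, corpora, authors, pairs)."""
    o, obo_text = generate_ontology(cfg)
    genes_by_genome, author_map, mill = generate_corpora(cfg, o)
    pairs, truth = generate_families(cfg, o, genes_by_genome, mill)
    return Scenario(
        config=cfg, ontology=o, obo_text=obo_text,
        genes_by_genome=genes_by_genome, author_map=dict(mill.author_map),
        pairs=pairs, truth=truth,
    )


def write_scenario(scn: Scenario, outdir) -> dict[str, Path]:
    """Write the scenario as standard flat files.

    ``ontology.obo``, one GAF 2.2 file per genome, ``authors.tsv``
    (reference TAB semicolon-joined authors), ``pairs.tsv`` and
    ``truth.tsv``; all byte-deterministic under a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["obo"] = outdir / "ontology.obo"
    files["obo"].write_text(scn.obo_text)

    for genome, genes in sorted(scn.genes_by_genome.items()):
        lines = ["!gaf-version: 2.2"]
        for gene in sorted(genes):
            for r in genes[gene].records:
                lines.append("\t".join([
                    "SYNTH", r.gene, r.gene, "enables", r.term, r.reference,
                    r.evidence, "", _namespace_code(scn.ontology, r.term),
                    "", "", "protein", f"taxon:{genome}", "20120101", "SYNTH",
                    "", "",
                ]))
        path = outdir / f"{genome}.gaf"
        path.write_text("\n".join(lines) + "\n")
        files[f"gaf:{genome}"] = path

    files["authors"] = outdir / "authors.tsv"
    files["authors"].write_text(
        "".join(
            f"{ref}\t{';'.join(sorted(authors))}\n"
            for ref, authors in sorted(scn.author_map.items())
        )
    )

    files["pairs"] = outdir / "pairs.tsv"
    pd.DataFrame(
        [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "genome_a": p.genome_a,
             "genome_b": p.genome_b, "subtype": p.subtype,
             "percent_identity": p.percent_identity, "family": p.family}
            for p in scn.pairs
        ]
    ).to_csv(files["pairs"], sep="\t", index=False)

    files["truth"] = outdir / "truth.tsv"
    scn.truth.to_csv(files["truth"], sep="\t", index=False)
    return files


def _namespace_code(o: Ontology, term: str) -> str:
    return {"molecular_function": "F", "biological_process": "P",
            "cellular_component": "C"}[o.namespace_of[term]]
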