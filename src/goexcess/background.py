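"""Background similarity estimation and excess similarity.

Raw semantic similarity is not comparable across genome pairs or homology
subtypes: annotation coverage, term-usage profiles and the functional
composition of e.g. duplicated vs. single-copy genes all shift the
similarity of *random* gene pairs.  The background table therefore holds,
for every (genome pair — including self-pairs — , homology subtype,
namespace) stratum, the mean similarity of random gene pairs sampled with
replacement from the genes eligible for that stratum: genes that (i)
participate in at least one homolog pair of that subtype for that genome
pair and (ii) are annotated.  Excess similarity is the raw gene-pair
similarity minus the stratum background, and may be negative.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneAnnotationSet
from .homology import HomologPair
from .similarity import ContextStore, MeasureConfig, combined_similarity

log = logging.getLogger(__name__)

COMBINED = "combined"

#: stratum key: (genome_i, genome_j, subtype) with the genome pair sorted
Stratum = tuple[str, str, str]


def stratum_of(pair: HomologPair) -> Stratum:
    gi, gj = sorted([pair.genome_a, pair.genome_b])
    return (gi, gj, pair.subtype)


@dataclass
class BackgroundTable:
    """Mean random-pair similarity per (genome pair, subtype, namespace)."""

    entries: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    n_used: dict[tuple[str, str, str, str], int] = field(default_factory=dict)
    n_samples: int = 0
    seed: int = 0

    def get(self, pair: HomologPair, namespace: str = COMBINED) -> float | None:
        gi, gj, sub = stratum_of(pair)
        return self.entries.get((gi, gj, sub, namespace))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genome_i": k[0], "genome_j": k[1], "subtype": k[2], "namespace": k[3],
             "mean_similarity": v, "n": self.n_used.get(k, self.n_samples)}
            for k, v in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["genome_i", "genome_j", "subtype", "namespace",
                           "mean_similarity", "n"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BackgroundTable":
        df = pd.read_csv(path, sep="\t", dtype={"genome_i": str, "genome_j": str})
        t = cls()
        for row in df.itertuples(index=False):
            k = (row.genome_i, row.genome_j, row.subtype, row.namespace)
            t.entries[k] = float(row.mean_similarity)
            t.n_used[k] = int(row.n)
        return t


def eligible_genes(
    pairs: Iterable[HomologPair],
    genes_by_genome: Mapping[str, Mapping[str, GeneAnnotationSet]],
) -> dict[Stratum, tuple[list[str], list[str]]]:
    """Per stratum, the sorted eligible gene lists for each genome side.

    A gene is eligible if it appears in at least one homolog pair of the
    stratum's subtype between the stratum's genomes and is annotated.
    """
    members: dict[Stratum, tuple[set[str], set[str]]] = {}
    for p in pairs:
        st = stratum_of(p)
        side_a, side_b = members.setdefault(st, (set(), set()))
        for genome, gene in ((p.genome_a, p.gene_a), (p.genome_b, p.gene_b)):
            if gene not in genes_by_genome.get(genome, {}):
                continue
            if genome == st[0]:
                side_a.add(gene)
            if genome == st[1]:
                side_b.add(gene)
    return {st: (sorted(a), sorted(b)) for st, (a, b) in members.items()}


def _stratum_seed(master_seed: int, stratum: Stratum) -> np.random.Generator:
    """Deterministic per-stratum substream: adding a stratum never shifts
    the draws of another."""
    tag = zlib.crc32("\t".join(stratum).encode())
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(tag,)))


def sample_stratum_pairs(
    rng: np.random.Generator,
    elig_a: Sequence[str],
    elig_b: Sequence[str],
    n: int,
) -> list[tuple[str, str]]:
    """Draw n unordered random gene pairs with replacement, one gene per
    genome side (for same-species strata both sides are the same set)."""
    ia = rng.integers(len(elig_a), size=n)
    ib = rng.integers(len(elig_b), size=n)
    return [(elig_a[i], elig_b[j]) for i, j in zip(ia, ib)]


def mean_pair_similarity(
    gene_pairs: Iterable[tuple[GeneAnnotationSet, GeneAnnotationSet]],
    contexts,
    config: MeasureConfig,
) -> tuple[dict[str, float], dict[str, int]]:
    """Mean per-namespace (and combined) similarity over gene pairs;
    pairs undefined in a namespace are excluded from that namespace's mean."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ga, gb in gene_pairs:
        per_ns, combined = combined_similarity(ga, gb, contexts, config)
        if combined is not None:
            per_ns = dict(per_ns)
            per_ns[COMBINED] = combined
        for ns, v in per_ns.items():
            sums[ns] = sums.get(ns, 0.0) + v
            counts[ns] = counts.get(ns, 0) + 1
    return (
        {ns: sums[ns] / counts[ns] for ns in sums if counts[ns] > 0},
        counts,
    )


def estimate_background(
    genes_by_genome: Mapping[str, Mapping[str, GeneAnnotationSet]],
    pairs: Sequence[HomologPair],
    store: ContextStore,
    config: MeasureConfig | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> BackgroundTable:
    """Mean similarity of ``n`` random gene pairs per stratum.

    Reproducible given ``seed``; strata with fewer than two eligible
    genes in total get no entry (their homolog pairs are later skipped
    with a warning).
    """
    config = (config or MeasureConfig()).validate()
    table = BackgroundTable(n_samples=n, seed=seed)
    for stratum, (elig_a, elig_b) in sorted(eligible_genes(pairs, genes_by_genome).items()):
        gi, gj, subtype = stratum
        if len(set(elig_a) | set(elig_b)) < 2 or not elig_a or not elig_b:
            log.warning("background: stratum %s has < 2 eligible genes, skipped", stratum)
            continue
        rng = _stratum_seed(seed, stratum)
        sampled = sample_stratum_pairs(rng, elig_a, elig_b, n)
        contexts = store.get(gi, gj)
        gene_pairs = (
            (genes_by_genome[gi][a], genes_by_genome[gj][b]) for a, b in sampled
        )
        means, counts = mean_pair_similarity(gene_pairs, contexts, config)
        for ns, m in means.items():
            table.entries[(gi, gj, subtype, ns)] = m
            table.n_used[(gi, gj, subtype, ns)] = counts[ns]
    return table


def excess_similarity(
    pair: HomologPair,
    raw: float,
    bg: BackgroundTable,
    namespace: str = COMBINED,
) -> float | None:
    """Raw similarity minus the pair's stratum background (may be negative).

    Returns None when the stratum has no background entry; callers skip
    and count such pairs.
    """
    base = bg.get(pair, namespace)
    if base is None:
        return None
    return raw - base
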