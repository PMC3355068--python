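"""Homolog pairs: loading, subtype vocabulary, identity cutoff and binning.

Pairs arrive pre-labeled (e.g. exported from OMA or Ensembl Compara) with
one of four homology subtypes: one-to-one orthologs, other (one-to-many /
many-to-many) orthologs, in-paralogs (by construction within one species)
and out-paralogs (within or between species).  Percent identity over the
full protein sequences is the evolutionary-divergence axis; pairs at or
below the cutoff (default 10%) are discarded and the rest tiled into
identity bins with a lower-exclusive/upper-inclusive convention, so the
cutoff and the first bin edge coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import PairValidationError

SUBTYPES = ("ortholog_1to1", "ortholog_other", "inparalog", "outparalog")
ORTHOLOG_SUBTYPES = frozenset({"ortholog_1to1", "ortholog_other"})
PARALOG_SUBTYPES = frozenset({"inparalog", "outparalog"})

_AA = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO")


@dataclass(frozen=True)
class HomologPair:
    """A typed, identity-scored homologous gene pair (unordered)."""

    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str
    subtype: str
    percent_identity: float
    family: str | None = None
    divergence_time: float | None = None

    @property
    def same_species(self) -> bool:
        return self.genome_a == self.genome_b

    @property
    def key(self) -> tuple:
        """Order-invariant pair identity."""
        a, b = sorted([(self.genome_a, self.gene_a), (self.genome_b, self.gene_b)])
        return (a, b, self.subtype)

    def validate(self) -> "HomologPair":
        if self.subtype not in SUBTYPES:
            raise PairValidationError(
                f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}"
            )
        if not (0 < self.percent_identity <= 100):
            raise PairValidationError(
                f"percent identity {self.percent_identity} outside (0, 100]"
            )
        if self.subtype == "inparalog" and not self.same_species:
            raise PairValidationError(
                f"inparalog pair {self.gene_a}/{self.gene_b} spans two species"
            )
        if self.subtype in ORTHOLOG_SUBTYPES and self.same_species:
            raise PairValidationError(
                f"ortholog pair {self.gene_a}/{self.gene_b} within one species"
            )
        return self


@dataclass(frozen=True)
class IdentityBin:
    """A percent-identity bin (lower, upper]."""

    lower: float
    upper: float

    @property
    def label(self) -> str:
        return f"({self.lower:g},{self.upper:g}]"

    def __contains__(self, identity: float) -> bool:
        return self.lower < identity <= self.upper


def parse_pairs(path) -> list[HomologPair]:
    """Load homolog pairs from TSV; validates invariants and collapses
    duplicated (possibly reversed) pairs."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str,
                                            "genome_a": str, "genome_b": str})
    required = ["gene_a", "gene_b", "genome_a", "genome_b", "subtype", "percent_identity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PairValidationError(f"pair table missing columns: {missing}")
    pairs: list[HomologPair] = []
    seen: set[tuple] = set()
    for row in df.itertuples(index=False):
        p = HomologPair(
            gene_a=row.gene_a, gene_b=row.gene_b,
            genome_a=row.genome_a, genome_b=row.genome_b,
            subtype=row.subtype, percent_identity=float(row.percent_identity),
            family=str(row.family) if "family" in df.columns and pd.notna(row.family) else None,
            divergence_time=float(row.divergence_time)
            if "divergence_time" in df.columns and pd.notna(row.divergence_time) else None,
        ).validate()
        if p.key in seen:
            continue
        seen.add(p.key)
        pairs.append(p)
    return pairs


def apply_identity_cutoff(
    pairs: Iterable[HomologPair], cutoff: float = 10.0
) -> list[HomologPair]:
    """Keep pairs with strictly more than ``cutoff`` percent identity."""
    return [p for p in pairs if p.percent_identity > cutoff]


def make_bins(width: float = 10.0, lower: float = 10.0, upper: float = 100.0) -> list[IdentityBin]:
    """Tile (lower, upper] into bins of the given width (last bin truncated)."""
    bins = []
    lo = lower
    while lo < upper - 1e-9:
        hi = min(lo + width, upper)
        bins.append(IdentityBin(lower=round(lo, 9), upper=round(hi, 9)))
        lo = hi
    return bins


def assign_bin(identity: float, width: float = 10.0, lower: float = 10.0,
               upper: float = 100.0) -> IdentityBin:
    """The unique bin with lower < identity <= upper."""
    if not (lower < identity <= upper):
        raise ValueError(f"identity {identity} outside ({lower}, {upper}]")
    i = math.ceil((identity - lower) / width - 1e-12) - 1
    return IdentityBin(
        lower=round(lower + i * width, 9),
        upper=round(min(lower + (i + 1) * width, upper), 9),
    )


def bin_pairs(
    pairs: Iterable[HomologPair], width: float = 10.0, lower: float = 10.0,
) -> dict[IdentityBin, list[HomologPair]]:
    """Partition pairs into identity bins; every pair lands in exactly one."""
    out: dict[IdentityBin, list[HomologPair]] = {}
    for p in pairs:
        b = assign_bin(p.percent_identity, width=width, lower=lower)
        out.setdefault(b, []).append(p)
    return out


def compute_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    denominator: str = "alignment",
) -> float:
    """Percent identity from a local (Smith–Waterman) protein alignment.

    ``denominator`` selects the identity convention: ``alignment`` divides
    by the number of alignment columns (gaps included), ``shorter`` by the
    length of the shorter input sequence.  Sequence pairs with no
    positive-scoring local alignment score 0% (removed later by cutoff).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq.upper()) - _AA
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters: {sorted(bad)}")
    if denominator not in ("alignment", "shorter"):
        raise ValueError(f"unknown identity denominator {denominator!r}")

    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(matrix),
        open_gap_score=-gap_open,
        extend_gap_score=-gap_extend,
    )
    sa, sb = seq_a.upper(), seq_b.upper()
    if aligner.score(sa, sb) <= 0:
        return 0.0
    aln = aligner.align(sa, sb)[0]
    counts = aln.counts()
    n_cols = counts.gaps + counts.identities + counts.mismatches
    denom = n_cols if denominator == "alignment" else min(len(sa), len(sb))
    return 100.0 * counts.identities / denom
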