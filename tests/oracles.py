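"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and self-contained: ancestor
closures by repeated edge relaxation to a fixpoint, term frequencies by
explicit propagation, similarity by exhaustive matrix enumeration, and
Mann-Whitney p-values by full enumeration of labelings.  None of it
imports the package's own graph, similarity or statistics code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata


# -- graph closure by fixpoint relaxation ----------------------------------

def closure_by_relaxation(parents: dict[str, set[str]], term: str) -> set[str]:
    """Reflexive ancestor set via repeated relaxation to a fixpoint."""
    closed = {term}
    changed = True
    while changed:
        changed = False
        for t in list(closed):
            for p in parents.get(t, ()):  # noqa: B905
                if p not in closed:
                    closed.add(p)
                    changed = True
    return closed


def random_dag(rng: np.random.Generator, n_terms: int, namespace: str = "biological_process"):
    """Random rooted DAG as a plain parents dict (term -> set of parents)."""
    ids = [f"T{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = 1 + (rng.random() < 0.3 and i >= 2)
        parents[ids[i]] = {ids[int(j)] for j in rng.choice(i, size=min(k, i), replace=False)}
    return ids, parents


# -- frequencies by explicit propagation -----------------------------------

def term_probabilities(
    gene_term_sets: list[set[str]], parents: dict[str, set[str]]
) -> tuple[dict[str, float], int]:
    """p(term) = fraction of genes whose propagated set contains the term."""
    total = len(gene_term_sets)
    counts: dict[str, int] = {}
    for terms in gene_term_sets:
        propagated: set[str] = set()
        for t in terms:
            propagated |= closure_by_relaxation(parents, t)
        for t in propagated:
            counts[t] = counts.get(t, 0) + 1
    return {t: c / total for t, c in counts.items()}, total


def p_or_min(p: dict[str, float], total: int, term: str) -> float:
    return p.get(term, 0.0) or (1.0 / total)


# -- term-level similarity -------------------------------------------------

def resnik(
    c_i: str, c_j: str, parents: dict[str, set[str]],
    p_a: dict[str, float], tot_a: int, p_b: dict[str, float], tot_b: int,
) -> float:
    common = closure_by_relaxation(parents, c_i) & closure_by_relaxation(parents, c_j)
    best = 0.0
    for a in common:
        pbar = 0.5 * (p_or_min(p_a, tot_a, a) + p_or_min(p_b, tot_b, a))
        best = max(best, -math.log(pbar))
    return best


def lin(
    c_i: str, c_j: str, parents: dict[str, set[str]],
    p_a: dict[str, float], tot_a: int, p_b: dict[str, float], tot_b: int,
) -> float:
    num = 2.0 * resnik(c_i, c_j, parents, p_a, tot_a, p_b, tot_b)
    den = -math.log(p_or_min(p_a, tot_a, c_i)) - math.log(p_or_min(p_b, tot_b, c_j))
    if den <= 0:
        return 0.0
    return min(1.0, max(0.0, num / den))


# -- gene-level similarity by exhaustive matrix enumeration ----------------

def gene_similarity(p_i, p_j, term_sim, mode: str) -> float:
    p_i, p_j = sorted(set(p_i)), sorted(set(p_j))
    matrix = {(x, y): term_sim(x, y) for x in p_i for y in p_j}
    if mode == "max":
        return max(matrix.values())
    if mode == "avg":
        return sum(matrix.values()) / len(matrix)
    best_i = {x: max(matrix[(x, y)] for y in p_j) for x in p_i}
    best_j = {y: max(matrix[(x, y)] for x in p_i) for y in p_j}
    if mode == "schlicker_annotation":
        return (sum(best_i.values()) + sum(best_j.values())) / (len(p_i) + len(p_j))
    if mode == "schlicker_geneproduct":
        return 0.5 * (
            sum(best_i.values()) / len(p_i) + sum(best_j.values()) / len(p_j)
        )
    raise ValueError(mode)


def maryland_bridge(p_i, p_j, parents: dict[str, set[str]], roots: set[str]) -> float | None:
    s_i: set[str] = set()
    for t in p_i:
        s_i |= closure_by_relaxation(parents, t)
    s_j: set[str] = set()
    for t in p_j:
        s_j |= closure_by_relaxation(parents, t)
    s_i, s_j = s_i - roots, s_j - roots
    if not s_i or not s_j:
        return None
    return len(s_i & s_j) / 2.0 * (1.0 / len(s_i) + 1.0 / len(s_j))


# -- exact Mann-Whitney by enumeration of all labelings --------------------

def mannwhitney_exact_p(x, y) -> float:
    """Two-sided p: 2*min tail of the permutation distribution of U
    (average ranks), over all C(n+m, n) group labelings."""
    pooled = np.asarray(list(x) + list(y), float)
    n, m = len(x), len(y)
    ranks = rankdata(pooled)

    def u_of(idx) -> float:
        return float(ranks[list(idx)].sum() - n * (n + 1) / 2)

    u_obs = u_of(range(n))
    us = np.array([u_of(c) for c in itertools.combinations(range(n + m), n)])
    p_le = float(np.mean(us <= u_obs + 1e-9))
    p_ge = float(np.mean(us >= u_obs - 1e-9))
    return min(1.0, 2.0 * min(p_le, p_ge))


# -- local alignment identity by explicit Gotoh dynamic programming --------

def sw_identity(
    a: str, b: str, matrix, gap_open: float, gap_extend: float,
    denominator: str = "alignment",
) -> float:
    """Percent identity of the optimal local alignment, full O(nm) DP.

    Affine gaps: a gap of length L costs gap_open + (L-1)*gap_extend.
    ``matrix`` is a Biopython substitution matrix used only for lookups.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, :] = M[:, 0] = NEG
    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1], 0.0) + s
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            if M[i, j] > best:
                best, best_ij = M[i, j], (i, j)
    if best_ij is None:
        return 0.0
    # traceback from the best match cell
    i, j = best_ij
    state = "M"
    matches = cols = 0
    while i > 0 and j > 0:
        if state == "M":
            cols += 1
            matches += a[i - 1] == b[j - 1]
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1], 0.0)
            if prev == 0.0:
                i, j = i - 1, j - 1
                break
            if prev == M[i - 1, j - 1]:
                state = "M"
            elif prev == Ix[i - 1, j - 1]:
                state = "Ix"
            else:
                state = "Iy"
            i, j = i - 1, j - 1
        elif state == "Ix":
            cols += 1
            state = "M" if Ix[i, j] == M[i - 1, j] - gap_open else "Ix"
            i -= 1
        else:
            cols += 1
            state = "M" if Iy[i, j] == M[i, j - 1] - gap_open else "Iy"
            j -= 1
    denom = cols if denominator == "alignment" else min(n, m)
    return 100.0 * matches / denom


# -- exhaustive background expectation -------------------------------------

def exhaustive_mean_similarity(genes_a, genes_b, pair_sim) -> float:
    """Mean similarity over the full cartesian product of gene pairs."""
    vals = [pair_sim(ga, gb) for ga in genes_a for gb in genes_b]
    vals = [v for v in vals if v is not None]
    return sum(vals) / len(vals)
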