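"""Statistical battery over excess similarities.

Stratified means with normal-approximation 95% confidence intervals,
bin-wise two-sided Mann–Whitney U tests between orthologs and paralogs
(exact enumeration for small groups, tie-corrected normal approximation
otherwise), Kruskal–Wallis and planned Welch t-test contrasts between
homology subtypes, Spearman correlations of excess similarity with
sequence identity and divergence time, capped-resampling robustness
controls, and the triplet-restricted one-to-one ortholog comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .homology import IdentityBin, ORTHOLOG_SUBTYPES, PARALOG_SUBTYPES

Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: group sizes up to which the Mann-Whitney null is enumerated exactly
EXACT_MW_MAX = 8


@dataclass
class StratumSummary:
    """Mean excess similarity of one stratum with its 95% CI."""

    subtype: str
    bin: IdentityBin | None
    n: int
    mean: float
    ci_low: float
    ci_high: float
    degenerate: bool = False  # n == 1: CI undefined, bounds at the point value


@dataclass
class BinTestResult:
    """Bin-wise ortholog-vs-paralog comparison."""

    bin: IdentityBin
    n_orthologs: int
    n_paralogs: int
    diff_means: float  # orthologs − paralogs
    diff_ci_low: float
    diff_ci_high: float
    u_statistic: float
    p_value: float
    p_holm: float | None = None


def _mean_ci(values: Sequence[float]) -> tuple[int, float, float, float, bool]:
    v = np.asarray(values, dtype=float)
    n = v.size
    m = float(v.mean())
    if n < 2:
        return n, m, m, m, True
    se = float(v.std(ddof=1)) / np.sqrt(n)
    return n, m, m - Z95 * se, m + Z95 * se, False


def summarize_strata(
    groups: Mapping[tuple[str, IdentityBin | None], Sequence[float]],
) -> list[StratumSummary]:
    """Mean and normal-approximation 95% CI per (subtype, bin) group.

    Empty groups are absent; singletons are flagged degenerate with both
    CI bounds at the point value.
    """
    out = []
    for (subtype, b), values in groups.items():
        if len(values) == 0:
            continue
        n, m, lo, hi, degen = _mean_ci(values)
        out.append(StratumSummary(subtype, b, n, m, lo, hi, degen))
    out.sort(key=lambda s: (s.subtype, (s.bin.lower if s.bin else -1.0)))
    return out


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U; exact null for small groups.

    Both groups of size <= 8: exact enumeration (scipy's exact
    distribution without ties, full-permutation enumeration with ties);
    otherwise the tie-corrected normal approximation.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) <= EXACT_MW_MAX and len(y) <= EXACT_MW_MAX:
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if has_ties and min(len(x), len(y)) >= 2:
            method = sps.PermutationMethod(n_resamples=200_000, rng=0)
        else:
            # the permutation path needs >= 2 observations per group; for
            # singleton groups fall back to the tie-uncorrected exact null
            method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (reported alongside raw p-values)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def mannwhitney_by_bin(
    orthologs: Mapping[IdentityBin, Sequence[float]],
    paralogs: Mapping[IdentityBin, Sequence[float]],
) -> list[BinTestResult]:
    """Two-sided Mann–Whitney per identity bin (orthologs vs paralogs).

    Bins where either group is empty are skipped.  Raw p-values are
    primary; Holm-adjusted values are attached for reference.  The CI of
    the mean difference is the Welch normal approximation.
    """
    results = []
    for b in sorted(set(orthologs) & set(paralogs), key=lambda b: b.lower):
        xo, xp = list(orthologs[b]), list(paralogs[b])
        if not xo or not xp:
            continue
        u, p = mann_whitney(xo, xp)
        vo, vp = np.asarray(xo, float), np.asarray(xp, float)
        diff = float(vo.mean() - vp.mean())
        se = float(
            np.sqrt(
                (vo.var(ddof=1) / len(vo) if len(vo) > 1 else 0.0)
                + (vp.var(ddof=1) / len(vp) if len(vp) > 1 else 0.0)
            )
        )
        results.append(
            BinTestResult(
                bin=b, n_orthologs=len(vo), n_paralogs=len(vp),
                diff_means=diff, diff_ci_low=diff - Z95 * se,
                diff_ci_high=diff + Z95 * se, u_statistic=u, p_value=p,
            )
        )
    for r, adj in zip(results, holm_adjust([r.p_value for r in results])):
        r.p_holm = adj
    return results


def global_tests(df: pd.DataFrame) -> dict[str, float]:
    """Kruskal–Wallis across subtypes plus planned Welch t contrasts.

    ``df`` needs columns ``subtype``, ``same_species`` and ``excess``.
    Contrasts: 1:1 orthologs vs all other homologs; all orthologs vs all
    paralogs; same- vs different-species paralogs.  Degenerate groups
    (< 2 values) drop the affected test from the output.
    """
    out: dict[str, float] = {}
    groups = [g["excess"].to_numpy() for _, g in df.groupby("subtype")]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) >= 2:
        out["kruskal_wallis_p"] = float(sps.kruskal(*groups).pvalue)

    def welch(a: np.ndarray, b: np.ndarray, name: str) -> None:
        if len(a) >= 2 and len(b) >= 2:
            out[name] = float(sps.ttest_ind(a, b, equal_var=False).pvalue)

    exc = df["excess"].to_numpy()
    is_11 = (df["subtype"] == "ortholog_1to1").to_numpy()
    is_orth = df["subtype"].isin(ORTHOLOG_SUBTYPES).to_numpy()
    is_para = df["subtype"].isin(PARALOG_SUBTYPES).to_numpy()
    same = df["same_species"].to_numpy(dtype=bool)
    welch(exc[is_11], exc[~is_11], "t_1to1_vs_other_homologs_p")
    welch(exc[is_orth], exc[is_para], "t_orthologs_vs_paralogs_p")
    welch(exc[is_para & same], exc[is_para & ~same], "t_same_vs_diff_species_paralogs_p")
    return out


def correlations(df: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Spearman correlations of excess similarity with divergence proxies.

    Identity correlation uses all homologs; divergence-time correlation
    (when the column is present and populated) only orthologs.  Constant
    inputs yield (nan, nan).
    """
    out: dict[str, tuple[float, float]] = {}

    def spear(a, b, name):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            out[name] = (float("nan"), float("nan"))
            return
        r = sps.spearmanr(a, b)
        out[name] = (float(r.statistic), float(r.pvalue))

    spear(df["percent_identity"], df["excess"], "spearman_identity")
    if "divergence_time" in df.columns:
        orth = df[df["subtype"].isin(ORTHOLOG_SUBTYPES)].dropna(subset=["divergence_time"])
        if len(orth) >= 3:
            spear(orth["divergence_time"], orth["excess"], "spearman_time")
    return out


def capped_resample(
    df: pd.DataFrame,
    cap_key: str,
    cap: int,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Robustness control against over-represented groups.

    Per repetition, every (``cap_key`` x subtype) group is down-sampled
    with replacement to at most ``cap`` pairs and per-subtype mean excess
    recomputed.  ``cap_key`` is ``species_pair`` or ``family``.  Returns
    a reps x subtypes matrix of means.
    """
    if cap < 1 or reps < 1:
        raise ValueError("cap and reps must be >= 1")
    work = df.copy()
    if cap_key == "species_pair":
        work["_capkey"] = [
            "|".join(sorted([a, b]))
            for a, b in zip(work["genome_a"], work["genome_b"])
        ]
    elif cap_key == "family":
        if "family" not in work.columns or work["family"].isna().any():
            raise ValueError("cap_key='family' requires family IDs on every pair")
        work["_capkey"] = work["family"]
    else:
        raise ValueError(f"unknown cap_key {cap_key!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subtypes = sorted(work["subtype"].unique())
    rows = []
    grouped = [
        (sub, g["excess"].to_numpy())
        for (sub, _), g in work.groupby(["subtype", "_capkey"])
    ]
    for _ in range(reps):
        pooled: dict[str, list[np.ndarray]] = {s: [] for s in subtypes}
        for sub, values in grouped:
            k = min(len(values), cap)
            pooled[sub].append(rng.choice(values, size=k, replace=True))
        rows.append(
            {s: float(np.concatenate(v).mean()) if v else float("nan")
             for s, v in pooled.items()}
        )
    return pd.DataFrame(rows, columns=subtypes)


def triplet_comparison(
    df: pd.DataFrame, genomes: tuple[str, str, str]
) -> list[StratumSummary]:
    """Excess similarity per genome-pair edge, restricted to gene triplets
    that are one-to-one orthologous along all three edges.

    ``df`` needs columns ``gene_a``, ``gene_b``, ``genome_a``,
    ``genome_b``, ``subtype``, ``excess``.  Returns one summary per edge
    (labelled ``"g1|g2"``); empty when no complete triplet exists.
    """
    ga, gb, gc = sorted(genomes)
    one2one = df[df["subtype"] == "ortholog_1to1"]

    def edge_map(x: str, y: str) -> dict[tuple[str, str], float]:
        out = {}
        for row in one2one.itertuples(index=False):
            pair = {row.genome_a: row.gene_a, row.genome_b: row.gene_b}
            if set(pair) == {x, y}:
                out[(pair[x], pair[y])] = float(row.excess)
        return out

    ab, ac, bc = edge_map(ga, gb), edge_map(ga, gc), edge_map(gb, gc)
    ab_of = {a: b for a, b in ab}
    ac_of = {a: c for a, c in ac}
    per_edge: dict[str, list[float]] = {
        f"{ga}|{gb}": [], f"{ga}|{gc}": [], f"{gb}|{gc}": []
    }
    for a, b in sorted(ab_of.items()):
        c = ac_of.get(a)
        if c is None or (b, c) not in bc:
            continue
        per_edge[f"{ga}|{gb}"].append(ab[(a, b)])
        per_edge[f"{ga}|{gc}"].append(ac[(a, c)])
        per_edge[f"{gb}|{gc}"].append(bc[(b, c)])
    if not any(per_edge.values()):
        import logging

        logging.getLogger(__name__).warning(
            "triplet_comparison: no complete 1:1 triplet among %s", genomes
        )
        return []
    return summarize_strata({(edge, None): v for edge, v in per_edge.items() if v})
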