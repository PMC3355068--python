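"""Stratified summaries, rank tests, correlations, resampling, triplets."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from goexcess.homology import IdentityBin
from goexcess.stats import (
    Z95,
    capped_resample,
    correlations,
    global_tests,
    holm_adjust,
    mann_whitney,
    mannwhitney_by_bin,
    summarize_strata,
    triplet_comparison,
)

from .oracles import mannwhitney_exact_p

B10 = IdentityBin(10, 20)
B20 = IdentityBin(20, 30)


class TestSummaries:
    def test_constant_group_has_zero_width_ci(self):
        (s,) = summarize_strata({("ortholog_1to1", B10): [0.3] * 20})
        assert s.mean == s.ci_low == s.ci_high == pytest.approx(0.3)
        assert s.n == 20 and not s.degenerate

    def test_bernoulli_group_ci_matches_hand_computation(self):
        values = [0.0] * 50 + [1.0] * 50
        (s,) = summarize_strata({("inparalog", B10): values})
        se = np.std(values, ddof=1) / np.sqrt(100)
        assert s.mean == pytest.approx(0.5)
        assert s.ci_low == pytest.approx(0.5 - Z95 * se)
        assert s.ci_high == pytest.approx(0.5 + Z95 * se)

    def test_singleton_is_degenerate(self):
        (s,) = summarize_strata({("outparalog", B20): [0.7]})
        assert s.degenerate and s.ci_low == s.ci_high == 0.7

    def test_empty_group_absent_and_output_sorted(self):
        out = summarize_strata({
            ("outparalog", B20): [0.1, 0.2],
            ("inparalog", B10): [],
            ("inparalog", B20): [0.4, 0.5],
        })
        assert [(s.subtype, s.bin.lower) for s in out] == [
            ("inparalog", 20), ("outparalog", 20),
        ]


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        """3-vs-3 with complete separation: exactly 2 of the C(6,3)=20
        labelings are as extreme, so the two-sided exact p is 0.1."""
        _, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("tie_prone", [False, True])
    def test_small_sample_p_equals_enumeration(self, tie_prone):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            nx, ny = rng.integers(2, 7, size=2)
            if tie_prone:
                x = rng.integers(0, 4, size=nx).astype(float)
                y = rng.integers(0, 4, size=ny).astype(float)
            else:
                x, y = rng.normal(size=nx), rng.normal(size=ny)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(mannwhitney_exact_p(x, y), abs=1e-9)

    def test_large_sample_shift_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1.0, 1.0, 200)
        y = rng.normal(0.0, 1.0, 200)
        _, p = mann_whitney(x, y)
        assert p < 1e-10


class TestHolm:
    def test_textbook_adjustment(self):
        raw = [0.01, 0.04, 0.03, 0.005]
        # sorted: 0.005*4=0.02, 0.01*3=0.03, 0.03*2=0.06, 0.04*1=0.06 (monotone)
        assert holm_adjust(raw) == pytest.approx([0.03, 0.06, 0.06, 0.02])

    def test_monotone_and_capped(self):
        raw = [0.9, 0.8, 0.5]
        adj = holm_adjust(raw)
        assert all(0 < a <= 1 for a in adj)
        # adjustment is weakly order-preserving (here all values cap at 1)
        order = np.argsort(raw)
        assert all(adj[order[k]] <= adj[order[k + 1]] for k in range(len(raw) - 1))
        assert max(adj) == 1.0


class TestByBin:
    def test_diff_and_holm_attached(self):
        orth = {B10: [0.5, 0.6, 0.7, 0.8], B20: [0.9, 1.0]}
        para = {B10: [0.1, 0.2, 0.3], B20: [0.3, 0.4]}
        results = mannwhitney_by_bin(orth, para)
        assert [r.bin for r in results] == [B10, B20]
        r = results[0]
        assert r.diff_means == pytest.approx(0.65 - 0.2)
        assert r.diff_ci_low < r.diff_means < r.diff_ci_high
        assert all(r.p_holm >= r.p_value for r in results)

    def test_one_sided_empty_bin_skipped(self):
        results = mannwhitney_by_bin({B10: [0.5], B20: [0.9]}, {B20: [0.3]})
        assert [r.bin for r in results] == [B20]


def frame(subtypes, excess, same_species=None, identities=None, **extra):
    n = len(excess)
    return pd.DataFrame({
        "subtype": subtypes,
        "excess": excess,
        "same_species": same_species if same_species is not None else [False] * n,
        "percent_identity": identities if identities is not None else
        np.linspace(15, 95, n),
        **extra,
    })


class TestGlobalTests:
    def test_identical_groups_not_significant(self):
        df = frame(
            ["ortholog_1to1"] * 4 + ["inparalog"] * 4,
            [0.1, 0.2, 0.3, 0.4] * 2,
            same_species=[False] * 4 + [True] * 4,
        )
        out = global_tests(df)
        assert out["t_orthologs_vs_paralogs_p"] == pytest.approx(1.0)
        assert out["kruskal_wallis_p"] > 0.9

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        df = frame(
            ["ortholog_1to1"] * 100 + ["ortholog_other"] * 100 + ["inparalog"] * 100,
            np.concatenate([
                rng.normal(0.6, 0.1, 100),
                rng.normal(0.4, 0.1, 100),
                rng.normal(0.2, 0.1, 100),
            ]),
            same_species=[False] * 200 + [True] * 100,
        )
        out = global_tests(df)
        assert out["kruskal_wallis_p"] < 1e-10
        assert out["t_1to1_vs_other_homologs_p"] < 1e-10
        assert out["t_orthologs_vs_paralogs_p"] < 1e-10

    def test_same_vs_diff_species_paralog_contrast(self):
        rng = np.random.default_rng(1)
        df = frame(
            ["inparalog"] * 50 + ["outparalog"] * 50,
            np.concatenate([rng.normal(0.5, 0.05, 50), rng.normal(0.2, 0.05, 50)]),
            same_species=[True] * 50 + [False] * 50,
        )
        assert global_tests(df)["t_same_vs_diff_species_paralogs_p"] < 1e-10

    def test_degenerate_groups_drop_tests(self):
        df = frame(["ortholog_1to1"], [0.5])
        assert global_tests(df) == {}


class TestCorrelations:
    def test_perfect_monotone(self):
        df = frame(["ortholog_1to1"] * 10, np.arange(10) / 10.0,
                   identities=np.linspace(20, 90, 10))
        rho, p = correlations(df)["spearman_identity"]
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_tie_heavy_matches_average_rank_oracle(self):
        """Spearman with ties equals the Pearson correlation of
        hand-assigned average ranks."""
        rng = np.random.default_rng(5)
        ident = rng.integers(2, 9, 40) * 10.0
        excess = np.round(rng.normal(0, 1, 40), 1) + ident / 100.0
        df = frame(["outparalog"] * 40, excess, identities=ident)
        rho, _ = correlations(df)["spearman_identity"]
        ra, rb = rankdata(ident, method="average"), rankdata(excess, method="average")
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expected)

    def test_constant_input_is_nan(self):
        df = frame(["inparalog"] * 5, [0.3] * 5, identities=[50.0] * 5)
        rho, p = correlations(df)["spearman_identity"]
        assert np.isnan(rho) and np.isnan(p)

    def test_divergence_time_uses_orthologs_only(self):
        # orthologs: time and excess perfectly anti-monotone;
        # paralogs carry a contradictory trend that must not leak in.
        df = frame(
            ["ortholog_1to1"] * 6 + ["inparalog"] * 6,
            list(np.linspace(0.9, 0.4, 6)) + list(np.linspace(0.1, 0.9, 6)),
            same_species=[False] * 6 + [True] * 6,
            divergence_time=list(np.linspace(10, 60, 6)) + list(np.linspace(10, 60, 6)),
        )
        rho, _ = correlations(df)["spearman_time"]
        assert rho == pytest.approx(-1.0)


class TestCappedResample:
    def base_frame(self):
        # family f1 dominates subtype s with constant value 1.0
        rows = (
            [("ortholog_1to1", "f1", 1.0)] * 100
            + [("ortholog_1to1", "f2", 0.0)] * 10
        )
        return pd.DataFrame(rows, columns=["subtype", "family", "excess"]).assign(
            genome_a="sp1", genome_b="sp2"
        )

    def test_cap_rebalances_dominant_family(self):
        """Values are constant within each family, so the capped mean is
        exactly the cap-weighted mixture regardless of sampling noise:
        min(100,10)/(10+10) = 0.5 versus the raw mean 100/110."""
        df = self.base_frame()
        out = capped_resample(df, cap_key="family", cap=10, reps=5, seed=0)
        assert np.allclose(out["ortholog_1to1"], 0.5)
        assert df["excess"].mean() == pytest.approx(100 / 110)

    def test_inactive_cap_preserves_group_weights(self):
        df = self.base_frame()
        out = capped_resample(df, cap_key="family", cap=1000, reps=3, seed=0)
        # every group keeps its full size, so the expectation is the raw
        # mean; with constant within-group values it is exact.
        assert np.allclose(out["ortholog_1to1"], 100 / 110)

    def test_species_pair_key_and_determinism(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "subtype": ["inparalog"] * 60,
            "genome_a": ["sp1"] * 40 + ["sp2"] * 20,
            "genome_b": ["sp1"] * 40 + ["sp2"] * 20,
            "excess": rng.normal(size=60),
        })
        a = capped_resample(df, cap_key="species_pair", cap=15, reps=4, seed=9)
        b = capped_resample(df, cap_key="species_pair", cap=15, reps=4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_family_ids_rejected(self):
        df = self.base_frame()
        df.loc[0, "family"] = None
        with pytest.raises(ValueError, match="family"):
            capped_resample(df, cap_key="family", cap=10)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            capped_resample(self.base_frame(), cap_key="family", cap=0)
        with pytest.raises(ValueError, match="cap_key"):
            capped_resample(self.base_frame(), cap_key="lab", cap=5)


class TestTriplets:
    def triplet_frame(self):
        rows = []
        # five complete triplets across sp1, sp2, sp3
        for k in range(5):
            a, b, c = f"a{k}", f"b{k}", f"c{k}"
            rows.append((a, b, "sp1", "sp2", "ortholog_1to1", 0.5 + 0.01 * k))
            rows.append((a, c, "sp1", "sp3", "ortholog_1to1", 0.4 + 0.01 * k))
            rows.append((b, c, "sp2", "sp3", "ortholog_1to1", 0.3 + 0.01 * k))
        # dangling pairs missing one edge must be excluded
        rows.append(("a9", "b9", "sp1", "sp2", "ortholog_1to1", 0.9))
        rows.append(("a9", "c9", "sp1", "sp3", "ortholog_1to1", 0.9))
        rows.append(("b8", "c8", "sp2", "sp3", "ortholog_1to1", 0.9))
        # non-1:1 pairs never participate
        rows.append(("a0", "b0x", "sp1", "sp2", "ortholog_other", 0.9))
        return pd.DataFrame(
            rows,
            columns=["gene_a", "gene_b", "genome_a", "genome_b", "subtype", "excess"],
        )

    def test_complete_triplets_per_edge(self):
        out = triplet_comparison(self.triplet_frame(), ("sp1", "sp2", "sp3"))
        assert len(out) == 3
        by_edge = {s.subtype: s for s in out}
        assert set(by_edge) == {"sp1|sp2", "sp1|sp3", "sp2|sp3"}
        assert all(s.n == 5 for s in out)
        assert by_edge["sp1|sp2"].mean == pytest.approx(np.mean([0.5 + 0.01 * k for k in range(5)]))

    def test_genome_order_invariance(self):
        df = self.triplet_frame()
        a = triplet_comparison(df, ("sp1", "sp2", "sp3"))
        b = triplet_comparison(df, ("sp3", "sp1", "sp2"))
        assert [(s.subtype, s.n, s.mean) for s in a] == [(s.subtype, s.n, s.mean) for s in b]

    def test_no_triplet_returns_empty(self):
        df = self.triplet_frame().iloc[:2]
        assert triplet_comparison(df, ("sp1", "sp2", "sp3")) == []
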