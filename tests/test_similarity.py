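"""Term- and gene-level semantic similarity measures."""

import math

import numpy as np
import pytest

from goexcess.annotations import term_frequencies
from goexcess.errors import UndefinedICError
from goexcess.ontology import build_ontology
from goexcess.similarity import (
    MeasureConfig,
    TermSimilarityContext,
    combined_similarity,
    maryland_bridge,
    sim_gene_pairing,
    sim_lin,
    sim_resnik,
)

from . import oracles
from .conftest import DAG1_PARENTS, NS, make_genes

MODES = ["max", "avg", "schlicker_annotation", "schlicker_geneproduct"]


class TestResnik:
    def test_root_mica_scores_zero(self, dag1_ctx):
        assert sim_resnik("A", "B", dag1_ctx) == 0.0

    def test_worked_fixture_value(self, dag1_ctx):
        # MICA of C and D is B with p = 0.8
        assert sim_resnik("C", "D", dag1_ctx) == pytest.approx(-math.log(0.8), abs=1e-12)
        assert dag1_ctx.mica("C", "D")[0] == "B"

    def test_reflexive_is_own_ic(self, dag1_ctx):
        assert sim_resnik("C", "C", dag1_ctx) == pytest.approx(-math.log(0.1))

    def test_absent_term_raises(self, dag1):
        genes = make_genes("sp1", [["A"], ["B"]])
        freq = term_frequencies(genes, dag1, "sp1")[NS]
        ctx = TermSimilarityContext(ontology=dag1, freq_a=freq, freq_b=freq)
        with pytest.raises(UndefinedICError):
            sim_resnik("D", "A", ctx)

    def test_deeper_mica_never_scores_lower(self, dag1_ctx):
        # (C, D) share B (p=0.8); (C, C) share C itself (p=0.1): the more
        # specific MICA has strictly higher IC
        assert sim_resnik("C", "C", dag1_ctx) > sim_resnik("C", "D", dag1_ctx)


class TestLin:
    def test_identical_specific_terms_score_one(self, dag1_ctx):
        assert sim_lin("C", "C", dag1_ctx) == pytest.approx(1.0)

    def test_worked_fixture_value(self, dag1_ctx):
        expected = 2 * (-math.log(0.8)) / ((-math.log(0.1)) + (-math.log(0.3)))
        assert sim_lin("C", "D", dag1_ctx) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1273, abs=5e-5)

    def test_root_pair_uses_zero_over_zero_convention(self, dag1_ctx):
        assert sim_lin("R", "R", dag1_ctx) == 0.0

    def test_bounded(self, dag1_ctx):
        for x in "RABCD":
            for y in "RABCD":
                assert 0.0 <= sim_lin(x, y, dag1_ctx) <= 1.0


class TestGenePairing:
    def test_identical_singletons_all_modes(self, dag1_ctx):
        for mode in MODES:
            assert sim_gene_pairing({"C"}, {"C"}, dag1_ctx, mode) == pytest.approx(1.0)

    def test_singletons_reduce_to_term_similarity(self, dag1_ctx):
        s_cd = sim_lin("C", "D", dag1_ctx)
        for mode in MODES:
            assert sim_gene_pairing({"C"}, {"D"}, dag1_ctx, mode) == pytest.approx(s_cd)

    def test_schlicker_annotation_on_2x1_matrix(self, dag1_ctx):
        # (best(C) + best(A) + best(D)) / 3, checked against the
        # exhaustive-matrix oracle
        expected = oracles.gene_similarity(
            ["A", "C"], ["D"],
            lambda x, y: sim_lin(x, y, dag1_ctx), "schlicker_annotation",
        )
        got = sim_gene_pairing(["A", "C"], ["D"], dag1_ctx, "schlicker_annotation")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_annotation_and_geneproduct_weightings_differ(self, dag1_ctx):
        """Asymmetric cardinalities weight the two genes differently."""
        p_i, p_j = ["A", "C", "D"], ["D"]
        ann = sim_gene_pairing(p_i, p_j, dag1_ctx, "schlicker_annotation")
        gp = sim_gene_pairing(p_i, p_j, dag1_ctx, "schlicker_geneproduct")
        for mode, got in [("schlicker_annotation", ann), ("schlicker_geneproduct", gp)]:
            expected = oracles.gene_similarity(
                p_i, p_j, lambda x, y: sim_lin(x, y, dag1_ctx), mode
            )
            assert got == pytest.approx(expected, abs=1e-12)
        assert ann != pytest.approx(gp)

    def test_empty_set_rejected(self, dag1_ctx):
        with pytest.raises(ValueError, match="non-empty"):
            sim_gene_pairing(set(), {"C"}, dag1_ctx)


class TestMarylandBridge:
    def test_identical_propagated_sets(self, dag1):
        assert maryland_bridge({"C"}, {"C"}, dag1) == 1.0

    def test_disjoint_after_root_removal(self, dag1):
        assert maryland_bridge({"A"}, {"D"}, dag1) == 0.0

    def test_worked_fixture_value(self, dag1):
        # S_C = {C,A,B}, S_D = {D,B}: 1/2 * (1/3 + 1/2) = 5/12
        assert maryland_bridge({"C"}, {"D"}, dag1) == pytest.approx(5 / 12, abs=1e-12)

    def test_root_only_annotation_skipped(self, dag1):
        assert maryland_bridge({"R"}, {"C"}, dag1) is None


@pytest.fixture(scope="module")
def three_ns():
    terms = {"R": NS, "X": NS, "Y": NS,
             "RM": "molecular_function", "M": "molecular_function",
             "RC": "cellular_component", "K": "cellular_component"}
    edges = [("X", "R", "is_a"), ("Y", "R", "is_a"),
             ("M", "RM", "is_a"), ("K", "RC", "is_a")]
    return build_ontology(terms, edges)


class TestCombined:
    def make_ctxs(self, o, term_lists_a, term_lists_b):
        fa = term_frequencies(make_genes("a", term_lists_a), o, "a")
        fb = term_frequencies(make_genes("b", term_lists_b), o, "b")
        from goexcess.similarity import ContextStore

        return ContextStore(o, {"a": fa, "b": fb}).get("a", "b")

    def test_single_namespace_combined_equals_it(self, three_ns):
        ctxs = self.make_ctxs(three_ns, [["X"], ["Y"]], [["X"], ["Y"]])
        gi = make_genes("a", [["X"]])[0]
        gj = make_genes("b", [["X"]])[0]
        per_ns, combined = combined_similarity(gi, gj, ctxs)
        assert set(per_ns) == {NS}
        assert combined == per_ns[NS] == pytest.approx(1.0)

    def test_weighted_mean_arithmetic(self, three_ns):
        """A namespace with twice the annotations gets twice the weight."""
        ctxs = self.make_ctxs(
            three_ns,
            [["X", "Y", "M", "K"], ["X", "M", "K"]],
            [["X", "Y", "M", "K"], ["Y", "M", "K"]],
        )
        gi = make_genes("a", [["X", "Y", "M", "K"]])[0]
        gj = make_genes("b", [["X", "Y", "M", "K"]])[0]
        per_ns, combined = combined_similarity(gi, gj, ctxs)
        # weights are the pair's term counts per namespace: 4 for BP, 2, 2
        expected = (4 * per_ns[NS] + 2 * per_ns["molecular_function"]
                    + 2 * per_ns["cellular_component"]) / 8
        assert combined == pytest.approx(expected, abs=1e-12)

    def test_unweighted_mean_option(self, three_ns):
        ctxs = self.make_ctxs(
            three_ns,
            [["X", "Y", "M"], ["X", "M"]],
            [["X", "Y", "M"], ["Y", "M"]],
        )
        gi = make_genes("a", [["X", "Y", "M"]])[0]
        gj = make_genes("b", [["X", "Y", "M"]])[0]
        cfg = MeasureConfig(combined_weighting="unweighted")
        per_ns, combined = combined_similarity(gi, gj, ctxs, cfg)
        assert combined == pytest.approx(sum(per_ns.values()) / len(per_ns))

    def test_no_shared_namespace_returns_none(self, three_ns):
        ctxs = self.make_ctxs(three_ns, [["X"], ["Y"]], [["M"], ["M"]])
        gi = make_genes("a", [["X"]])[0]
        gj = make_genes("b", [["M"]])[0]
        assert combined_similarity(gi, gj, ctxs) == ({}, None)


class TestOracleEquivalence:
    """All measures match the exhaustive brute-force oracle on random DAGs."""

    def _random_setup(self, rng, n_terms):
        ids, parents = oracles.random_dag(rng, n_terms)
        o = build_ontology(
            {t: NS for t in ids},
            [(c, p, "is_a") for c, ps in parents.items() for p in ps],
        )
        vocab = [t for t in ids if t != ids[0]] or ids
        corpus_a = [
            list(rng.choice(vocab, size=min(int(rng.integers(1, 4)), len(vocab)),
                            replace=False))
            for _ in range(12)
        ]
        corpus_b = [
            list(rng.choice(vocab, size=min(int(rng.integers(1, 4)), len(vocab)),
                            replace=False))
            for _ in range(12)
        ]
        fa = term_frequencies(make_genes("a", corpus_a), o, "a")[NS]
        fb = term_frequencies(make_genes("b", corpus_b), o, "b")[NS]
        ctx = TermSimilarityContext(ontology=o, freq_a=fa, freq_b=fb)
        p_a, _ = oracles.term_probabilities([set(t) for t in corpus_a], parents)
        p_b, _ = oracles.term_probabilities([set(t) for t in corpus_b], parents)
        return o, parents, ctx, p_a, p_b, corpus_a, corpus_b, ids

    def test_thirty_random_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            o, parents, ctx, p_a, p_b, ca, cb, ids = self._random_setup(
                rng, int(rng.integers(3, 31))
            )
            tot_a, tot_b = ctx.freq_a.total, ctx.freq_b.total

            def term_lin(x, y):
                return oracles.lin(x, y, parents, p_a, tot_a, p_b, tot_b)

            gi = set(ca[int(rng.integers(len(ca)))])
            gj = set(cb[int(rng.integers(len(cb)))])
            for x in sorted(gi):
                for y in sorted(gj):
                    assert ctx.sim_resnik(x, y) == pytest.approx(
                        oracles.resnik(x, y, parents, p_a, tot_a, p_b, tot_b), abs=1e-12
                    )
                    assert ctx.sim_lin(x, y) == pytest.approx(term_lin(x, y), abs=1e-12)
            for mode in MODES:
                assert sim_gene_pairing(gi, gj, ctx, mode) == pytest.approx(
                    oracles.gene_similarity(gi, gj, term_lin, mode), abs=1e-12
                )
            mb = maryland_bridge(gi, gj, o)
            mb_oracle = oracles.maryland_bridge(gi, gj, parents, {ids[0]})
            if mb_oracle is None:
                assert mb is None
            else:
                assert mb == pytest.approx(mb_oracle, abs=1e-12)


class TestProperties:
    def test_symmetry_under_gene_and_genome_swap(self, dag1, dag1_freq):
        rng = np.random.default_rng(11)
        genes_b = make_genes("sp2", [["C"], ["D"], ["A"], ["B"], ["C"]])
        fb = term_frequencies(genes_b, dag1, "sp2")[NS]
        ctx = TermSimilarityContext(ontology=dag1, freq_a=dag1_freq, freq_b=fb)
        rev = ctx.swapped()
        vocab = ["A", "B", "C", "D"]
        for _ in range(200):
            gi = set(rng.choice(vocab, size=int(rng.integers(1, 4)), replace=False))
            gj = set(rng.choice(vocab, size=int(rng.integers(1, 4)), replace=False))
            for mode in MODES:
                assert sim_gene_pairing(gi, gj, ctx, mode) == pytest.approx(
                    sim_gene_pairing(gj, gi, rev, mode), abs=1e-12
                )
            assert maryland_bridge(gi, gj, dag1) == pytest.approx(
                maryland_bridge(gj, gi, dag1), abs=1e-12
            )

    def test_self_similarity_is_maximal(self, dag1_ctx):
        for terms in ({"C"}, {"C", "D"}, {"A", "B", "D"}):
            assert sim_gene_pairing(terms, terms, dag1_ctx,
                                    "schlicker_annotation") == pytest.approx(1.0)
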