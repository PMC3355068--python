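"""Term- and gene-level semantic similarity on a tiny hand-checkable DAG.

The ontology is five terms in one namespace: root R, children A and B,
C below both A and B, D below B.  The corpus annotates ten genes
(2xA, 4xB, 1xC, 3xD), so after propagating annotations up the DAG the
term probabilities are p(R)=1.0, p(B)=0.8, p(A)=0.3, p(D)=0.3, p(C)=0.1,
and every similarity below can be verified with a pocket calculator.
"""

from goexcess import (
    AnnotationRecord,
    GeneAnnotationSet,
    TermSimilarityContext,
    build_ontology,
    maryland_bridge,
    sim_gene_pairing,
    term_frequencies,
)

NS = "biological_process"

ontology = build_ontology(
    {t: NS for t in "RABCD"},
    [("A", "R", "is_a"), ("B", "R", "is_a"), ("C", "A", "is_a"),
     ("C", "B", "is_a"), ("D", "B", "is_a")],
)

genes = []
for i, term in enumerate("AABBBBCDDD"):
    g = GeneAnnotationSet(gene=f"g{i}", genome="demo")
    g.records = [AnnotationRecord(gene=g.gene, genome="demo", term=term,
                                  evidence="IDA", reference="REF:0")]
    genes.append(g)

freq = term_frequencies(genes, ontology, "demo")[NS]
for term in "RABCD":
    print(f"p({term}) = {freq.p(term):.1f}   IC = {freq.ic(term):.4f} nats")

ctx = TermSimilarityContext(ontology, freq, freq)
print()
print(f"Resnik(C, D) = -ln p(MICA=B) = {ctx.sim_resnik('C', 'D'):.4f} nats")
print(f"Lin(C, D)    = 2*IC(B) / (IC(C) + IC(D)) = {ctx.sim_lin('C', 'D'):.4f}")
print(f"Maryland bridge({{C}}, {{D}}) = {maryland_bridge(['C'], ['D'], ontology):.4f}"
      "  (= 5/12)")

print()
print("gene-level pairings of term sets {A, C} vs {B, D} (Lin):")
for mode in ("max", "avg", "schlicker_annotation", "schlicker_geneproduct"):
    s = sim_gene_pairing(["A", "C"], ["B", "D"], ctx, mode=mode)
    print(f"  {mode:22s} {s:.4f}")
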