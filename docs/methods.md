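# Methods

This note records the measurement model, the defaults and why they were
chosen, what the synthetic generator does and does not validate, and the
numerical conventions. Everything stated here about behavior is backed by
a test in `tests/`; scenario sizes and parameters are this package's own
choices.

## Ontology and annotation model

The ontology is a rooted DAG per namespace (molecular_function,
biological_process, cellular_component). Ancestor queries and annotation
propagation traverse `is_a` and `part_of` only; other relations are
ignored. The ancestor closure is reflexive. Obsolete terms are excluded
at parse time and `alt_id` aliases resolved to canonical terms, so
downstream code never sees either. Validation rejects cycles,
cross-namespace edges, multiple roots per namespace, and terms that do
not reach exactly one namespace root.

Annotations are read from GAF 2.x; records with a NOT qualifier are
dropped, unknown terms are dropped with a log line. Evidence classes:
*experimental* = {EXP, IDA, IEP, IGI, IMP, IPI}, *uncurated* = {IEA},
*curated* = everything else. The default analysis uses experimental
only, and evidence filtering happens before frequency estimation so
information content is computed on exactly the analyzed corpus.

## Term frequencies and similarity

Term probability is per genome: p_g(c) = fraction of annotated genes in
genome g whose propagated annotation set contains c (gene-level counting;
a term annotated to a gene twice counts once). p(root) = 1. Information
content is −ln p (nats). A term absent from a corpus falls back to the
smallest representable frequency, 1/(number of annotated genes).

Term similarity between annotation c_i (genome g_i) and c_j (genome
g_j):

- probability of a common ancestor a is symmetrized:
  p̄(a) = ½(p_{g_i}(a) + p_{g_j}(a)) (configurable to either single
  genome);
- Resnik = IC(MICA) under p̄; MICA ties on IC break to the
  lexicographically smallest term (score unaffected);
- Lin = 2·IC(MICA) / (IC_{g_i}(c_i) + IC_{g_j}(c_j)), clamped to [0, 1];
  a zero denominator (both terms universal) scores 0.

Gene-level pairing of term sets p_i × p_j: `max` and `avg` of the
term-pair matrix; two best-match averages — per annotation
(Σ row-max + Σ col-max)/(|p_i| + |p_j|) (the default,
`schlicker_annotation`) and per gene product
½(mean row-max + mean col-max); and the graph-only Maryland bridge
MB = |S_i ∩ S_j|/2 · (1/|S_i| + 1/|S_j|) on root-stripped propagated
sets (undefined, and the pair skipped, for root-only annotation).

Namespaces are combined as a weighted mean of per-namespace gene scores,
weight = number of distinct terms of the pair in that namespace; a
namespace contributes only when both genes are annotated in it.

## Background and excess similarity

Raw similarity is not comparable across genome pairs or subtypes, so
each analyzed pair is reported as excess = raw − background. The
background of a (genome pair, subtype) stratum is the mean similarity of
n = 10,000 random gene pairs (with replacement) drawn from the genes
that are annotated and participate in at least one homolog pair of that
stratum. Each stratum gets an independent RNG substream derived from the
master seed and the stratum label, so adding a stratum never shifts
another's draws. Excess may be negative; strata with fewer than two
eligible genes are skipped with a warning.

## Homology and bias controls

Pair subtypes: `ortholog_1to1`, `ortholog_other` (cross-species only),
`inparalog` (same species only), `outparalog` (either; reported split
into same-/different-species). Pairs at ≤ 10% alignment identity are
excluded (strictly greater passes); bins are lower-exclusive /
upper-inclusive, width 10 from 10. Percent identity, when computed
rather than supplied, uses Smith–Waterman local alignment (BLOSUM62,
gap 11/1) with identity = identities / alignment columns.

Authorship control: a pair classifies as `same_article` (shared
reference), `shared_author` (shared normalized author name), or
`disjoint_authors`. The main analysis restricts each pair's annotations
to the provenance-independent subsets: an annotation is dropped if its
reference or any author appears in the partner gene's *pre-filter*
provenance, symmetrically (order-independent and idempotent); the pair
is excluded if either side empties. A strict mode additionally excludes
pairs whose author data is missing, since sharing cannot be ruled out.

## Statistics

- Stratum means carry normal-approximation 95% CIs (±1.96·sd/√n);
  singletons are flagged degenerate.
- Bin-wise ortholog-vs-paralog comparisons use the two-sided
  Mann–Whitney U. Both groups ≤ 8: exact null (scipy's exact
  distribution without ties; full-permutation enumeration with ties;
  tie-uncorrected exact for singleton groups). Larger groups:
  tie-corrected normal approximation. Raw p-values are primary; Holm
  adjustments are attached for reference. The exact branch is tested
  against an independent enumeration of all C(n+m, n) labelings.
- Global comparisons: Kruskal–Wallis across subtypes plus planned Welch
  t contrasts (1:1 vs other homologs; orthologs vs paralogs; same- vs
  different-species paralogs).
- Spearman correlations of excess with percent identity (all pairs) and
  divergence time (orthologs only, when supplied).
- Robustness: repeated down-sampling to a cap per species pair (2,000)
  or family (100), 100 repetitions; and a triplet-restricted comparison
  that keeps only gene triplets one-to-one orthologous along all three
  edges of a genome triple.

## Synthetic generator

The generator exists to validate the pipeline, not to imitate biology.
Per scenario it draws: a random rooted DAG per namespace (emitted as OBO
text and re-parsed, so the file path is exercised); per-genome
annotation corpora whose term usage is Dirichlet-distributed around a
common base (concentration controls cross-genome divergence); a
lab/paper authorship process; and gene families with an ancestral term
set. A family member retains each ancestral term with probability
√(δ_subtype · exp(−λ(100 − identity)/100)) and otherwise replaces it
with a random term of similar depth, so a pair shares an ancestral term
with probability δ_eff and divergence changes *which* function is
annotated, not how specific it is. An optional co-paper channel copies
one member's terms onto a same-species partner through a shared paper —
the planted authorship bias. λ = 0 is the divergence-independent regime;
λ > 0 couples retention to identity.

Passing the acceptance battery therefore shows that the pipeline
recovers orderings, directions and null behavior planted under *this*
model. It does not show that real GO corpora satisfy the model, and no
claim about real data follows from it.

## Numerical conventions

- All ICs in nats; Lin, Maryland bridge and Schlicker-of-Lin in [0, 1].
- All randomness flows from one master seed through named
  `numpy.random.SeedSequence` substreams; every artifact is
  byte-deterministic under a fixed seed.
- Term-pair similarities are memoised per genome pair; background
  estimation and pair scoring share the cache.

## Limitations

- **Rank tests across strata.** Excess distributions contain atoms
  (families whose members share identical term sets produce identical
  similarity values), and each subtype's atoms are shifted by its own
  estimated background constant. Any difference between stratum
  backgrounds — even pure estimation noise — deterministically reorders
  atom masses, so Kruskal–Wallis across subtypes rejects under the null
  at large n. Mean-based contrasts are unaffected (background
  subtraction centers means by construction); calibration claims are
  therefore made for the Welch contrasts, and Kruskal–Wallis p-values
  should be read as descriptive for atom-laden data.
- **Background sampling noise** (SE ≈ sd/√10,000 per stratum) enters
  every excess value in a stratum as a common offset; comparisons
  between strata inherit it.
- The normal-approximation CIs are as good as their n; degenerate
  strata are flagged, not suppressed.
- The combined-namespace score weights namespaces by annotation counts;
  pairs annotated in disjoint namespaces are excluded rather than
  zero-filled, which conditions the analyzed set on annotation overlap.
- Percent identity depends on alignment parameters and the denominator
  convention; both are recorded in the manifest.
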