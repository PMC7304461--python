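# Methods

## Problem

Given a gene's ontology annotations — Gene Ontology (GO) terms with
evidence codes, Disease Ontology associations, anatomy-ontology
expression terms and human-ortholog calls — produce a short natural
language description. The hard step is compressing a large annotated
term set into at most `max_terms` display terms per category while
staying faithful: every display term must be an ancestor of (or equal
to) some annotated term, and together the display terms should *cover*
as many annotated terms as possible while remaining specific.

## Ontology model

An ontology is a DAG of terms with child→parent edges restricted to the
`is_a` and `part_of` relations; other relations (`regulates`,
`has_part`, …) are ignored because they do not support the
"sentence about a parent is true of the child" inference used for
grouping. Obsolete terms are dropped at load time; `alt_id`s resolve to
their primary term. Depth of a term is the **longest** path from the
root (a term reachable by both short and long routes is treated as
specific as its most specific placement). `leaves_under(t)` is the set
of leaf descendants of `t`, excluding `t` itself even when `t` is a
leaf; `ancestors(t)` excludes `t`.

## Candidate generation

For an initial (annotated) term set `I`:

* Every `t ∈ I` is a candidate covering `{t}`. Initial terms are exempt
  from the depth floor — a term a curator chose is displayable by
  definition.
* Every ancestor `a` of any `t ∈ I` with `depth(a) ≥ min_depth` is a
  candidate covering `{t ∈ I : a = t or a is an ancestor of t}`.
  The floor (default 3) excludes near-root terms such as
  "cellular process" that cover everything but say nothing.
* Blocklisted terms are removed from the candidate pool.

**LCA trimming** keeps only *minimal* covering candidates: a candidate
is discarded if some other candidate covering the same subset of `I`
is its descendant. This generalises the pairwise lowest common ancestor
to arbitrarily many terms; a term with no shared informative ancestor
is the LCA of itself. If at most `max_terms` minimal candidates remain
they are all selected (ordered by decreasing depth, then id); otherwise
selection falls through to the greedy cover below with unit weights.

**IC trimming** keeps the full candidate pool and weights each
candidate by its information content (below).

## Greedy weighted maximum coverage

Selection of up to `max_terms` candidates maximises covered initial
terms. Exact maximisation is NP-hard, so we use the standard greedy
algorithm: repeatedly pick the candidate maximising
`(newly covered count) × weight`, stopping when nothing new can be
covered. For nonnegative submodular coverage this is within a factor
(1 − 1/e) ≈ 0.632 of optimal; the test suite verifies the bound
empirically against an exhaustive oracle on instances with ≤ 20
candidates. Ties break deterministically: higher score, then greater
depth (more specific), then lexicographically smaller term id.

## Information content

All three measures use natural log and add-one smoothing so every
defined term has finite IC and the root has IC ≈ 0:

* `IC_corpus(t) = −log[(m(t)+1) / (Σ_u m(u)+1)]` from external usage
  counts `m` (used for evaluation only).
* `IC_annot(t) = −log[(g(t)+1) / (G+1)]`, where `g(t)` is the number of
  genes annotated to `t` or any descendant and `G` the number of
  annotated genes. Computed for all terms in one bottom-up pass
  accumulating gene sets over a topological order.
* `IC_sanchez(t) = −log[ (|leaves_under(t)| / |A(t)| + 1) / (L_max+1) ]`
  with `A(t) = ancestors(t) ∪ {t}` and `L_max` the ontology's total
  leaf count. Leaves score the maximum `log(L_max+1)`; purely
  structural, no annotation data needed.

Both graph-based measures are monotone non-increasing toward the root,
and trimming decisions are invariant to the logarithm base (a base
change rescales all weights by a common positive constant).

## Evidence handling

Evidence codes map to six ordered tiers: experimental (EXP, IDA, IPI,
IMP, IGI, IEP) ≻ high-throughput (HTP, HDA, HMP, HGI, HEP) ≻
phylogenetic (IBA, IBD, IKR, IRD) ≻ curator/author (IC, TAS, NAS) ≻
computational (ISS, ISO, ISA, ISM, IGC, RCA) ≻ electronic (IEA). Within
a gene and category only the best non-empty tier survives; if that tier
is phylogenetic, computational or electronic the sentence renders as a
prediction ("Predicted to …"). Unknown codes fall to the lowest tier
with a warning rather than failing. NOT-qualified annotations are
discarded.

## Sentence generation

Each category has a template (verb phrase, "several …, including"
phrase used when the display set is a strict compression, predicted
variant, qualifier phrases, optional "(multiple)" suffix used only for
grouped disease terms). Name joining: one name plain, two with " and ",
three or more with semicolons and "; and" before the last. Sentences
are emitted in a fixed category order ending with orthology and joined
with ". " plus a final period. Orthologs are ranked by the number of
supporting prediction methods; at most three are shown.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `max_terms` | 3 (5 for disease and expression) | sentence readability; disease/expression lists tolerate more items |
| `min_depth` | 3 | shallower GO/anatomy terms are essentially uninformative |
| trim algorithm | `ic_sanchez` per category; `lca` available | structural IC needs no corpus; LCA maximises coverage |
| prune direction | `keep_child` (expression: `keep_parent`) | direct annotations subsume ancestors; expression curation often lists substructures |
| evidence tiers | six-tier order above | standard curation practice |

## Synthetic fixtures

`genesum.fixtures` generates seeded random ontologies (topological
construction, each new node picks 1–3 earlier parents with weight
`rank**0.5`, giving depth distributions comparable to mid-size
bio-ontologies), gene→term assignments biased toward deep terms
(weight `depth²`, Poisson term counts), GAF/association/ortholog files
with a configurable evidence-tier mix, and corpus counts decaying with
depth. All randomness flows from `numpy.random.default_rng(seed)` with
fixed sub-seed offsets. The generator emulates the *shape* of real
inputs (DAG statistics, evidence mixes, file formats), not their
semantics: names are synthetic, and co-annotation structure is
independent across genes, so absolute benchmark numbers describe the
generator, not any real corpus.

## Evaluation

`compare_algorithms` trims every benchmark gene with each algorithm and
reports average coverage (% of initial terms covered), average depth
and average corpus IC of selected terms, plus two combined gains of
algorithm X over the LCA baseline:

```
gain = 100·(X_metric − LCA_metric)/LCA_metric − 100·(LCA_cov − X_cov)/LCA_cov
```

i.e. relative specificity improvement minus relative coverage loss.
Benchmarks use three ontologies of 150 terms with 500 genes each,
restricted to genes whose term count exceeds `max_terms` (the only
genes where trimming fires). These sizes are this package's own choice,
balancing statistical stability against test runtime.

## Limitations

* On the synthetic benchmark LCA coverage saturates near 100%, so
  coverage-dominance results there are necessary but weak evidence;
  real ontologies with blocklists and sparse deep regions are harsher.
* The gain formula mixes relative percentages of different quantities;
  it ranks algorithms but its magnitude has no absolute meaning.
* `part_of` is treated as fully transitive with `is_a` for coverage,
  a mild over-approximation for some anatomy assertions.
* Sentence realisation is template-bound English; no grammatical
  agreement beyond the provided phrase variants.
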