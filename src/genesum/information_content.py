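"""Information-content (IC) measures for ontology terms.

The IC of a term t is -log p(t); the three measures differ in how they
estimate p(t):

* ``ic_corpus`` — frequency of the term name (or any synonym) in a document
  corpus, add-one smoothed:  -log[(m(t)+1) / (Σ m + 1)].
* ``ic_annot`` — fraction of genes annotated to the term or any of its
  descendants, out of all annotated genes, add-one smoothed.
* ``ic_sanchez`` — a purely structural measure driven by the ratio of the
  term's leaf descendants to its subsumers (ancestors plus itself):
  -log[((|leaves(t)|/|A(t)|) + 1) / (maxleaves + 1)].

All values are in nats (natural log).  Trimming selections only compare IC
values against each other, so the log base is immaterial to which terms are
chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Set

from genesum.ontology import OntologyGraph


@dataclass
class CorpusFrequencies:
    """Term occurrence counts in a literature corpus.

    ``counts[t]`` is the number of times term t's name or any of its
    synonyms appears in the corpus; ``total`` is the sum over all terms.
    """

    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("corpus counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_tsv(cls, path: str) -> "CorpusFrequencies":
        """Read a precomputed ``term_id <TAB> count`` table."""
        counts: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term_id, count = line.split("\t")[:2]
                counts[term_id] = counts.get(term_id, 0) + int(count)
        return cls(counts)


@dataclass
class AnnotationCorpus:
    """Direct gene→term annotations used by the annotation-frequency IC."""

    gene_to_terms: Dict[str, Set[str]] = field(default_factory=dict)

    def annotated_genes(self, term_id: str) -> Set[str]:
        """Genes directly annotated to ``term_id``."""
        return {g for g, ts in self.gene_to_terms.items() if term_id in ts}

    def term_to_genes(self) -> Dict[str, Set[str]]:
        index: Dict[str, Set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                index.setdefault(t, set()).add(gene)
        return index

    def all_genes(self) -> Set[str]:
        return {g for g, ts in self.gene_to_terms.items() if ts}


def ic_corpus(term_id: str, freqs: CorpusFrequencies) -> float:
    """Corpus-frequency IC; an unseen term takes m(t)=0 (smoothed)."""
    m = freqs.counts.get(term_id, 0)
    return -math.log((m + 1) / (freqs.total + 1))


def ic_annot(
    term_id: str, graph: OntologyGraph, corpus: AnnotationCorpus
) -> float:
    """Annotation-frequency IC: genes under the term vs. all annotated genes."""
    term_id = graph.resolve(term_id)
    index = corpus.term_to_genes()
    genes = set(index.get(term_id, ()))
    for d in graph.descendants(term_id):
        genes |= index.get(d, set())
    n_total = len(corpus.all_genes())
    return -math.log((len(genes) + 1) / (n_total + 1))


def ic_annot_table(
    graph: OntologyGraph, corpus: AnnotationCorpus
) -> Dict[str, float]:
    """Annotation-frequency IC for every term, in one bottom-up pass."""
    import networkx as nx

    index = corpus.term_to_genes()
    n_total = len(corpus.all_genes())
    under: Dict[str, FrozenSet[str]] = {}
    table: Dict[str, float] = {}
    for t in nx.topological_sort(graph._g):  # children before parents
        genes: Set[str] = set(index.get(t, ()))
        for c in graph.children(t):
            genes |= under[c]
        under[t] = frozenset(genes)
        table[t] = -math.log((len(genes) + 1) / (n_total + 1))
    return table


def ic_sanchez(term_id: str, graph: OntologyGraph) -> float:
    """Structural IC (leaf-to-subsumer ratio); leaves share the maximum value."""
    term_id = graph.resolve(term_id)
    n_leaves_under = len(graph.leaves_under(term_id))
    n_subsumers = len(graph.ancestors(term_id)) + 1  # A(t) includes t itself
    maxleaves = len(graph.leaves())
    return -math.log((n_leaves_under / n_subsumers + 1) / (maxleaves + 1))


def ic_sanchez_table(graph: OntologyGraph) -> Dict[str, float]:
    """Structural IC for every term in the ontology."""
    return {t: ic_sanchez(t, graph) for t in graph}


def ic_corpus_table(graph: OntologyGraph, freqs: CorpusFrequencies) -> Dict[str, float]:
    return {t: ic_corpus(t, freqs) for t in graph}
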