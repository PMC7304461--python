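"""Ontology DAG loading and structural queries.

Ontologies (GO, Disease Ontology, anatomy ontologies) are held as directed
acyclic graphs with edges pointing from child to parent, restricted to the
``is_a`` and ``part_of`` relations — the only relations safe for grouping a
term under its ancestors.  Term depth is the length of the *longest* path
from a root, so that a term reachable both directly and through a more
specific route is placed at its most specific level.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

_SYNONYM_RE = re.compile(r'"([^"]*)"')


class OntologyError(Exception):
    """Base class for ontology loading/query failures."""


class UnknownTermError(KeyError, OntologyError):
    """Raised when a query references a term absent from the graph."""


class CycleError(ValueError, OntologyError):
    """Raised when the retained relations contain a cycle."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term (non-obsolete after loading)."""

    term_id: str
    name: str
    synonyms: Tuple[str, ...] = ()
    obsolete: bool = False


class OntologyGraph:
    """A rooted DAG of ontology terms with typed child→parent edges.

    Parameters
    ----------
    terms
        Mapping from term id to :class:`OntologyTerm`.
    edges
        Iterable of ``(child_id, parent_id, relation)`` triples.
    alt_ids
        Optional mapping from alternate (merged) ids to canonical ids,
        consulted by :meth:`resolve`.
    """

    def __init__(
        self,
        terms: Mapping[str, OntologyTerm],
        edges: Iterable[Tuple[str, str, str]],
        alt_ids: Mapping[str, str] | None = None,
        name: str = "",
    ) -> None:
        self.name = name
        self.terms: Dict[str, OntologyTerm] = dict(terms)
        self.alt_ids: Dict[str, str] = dict(alt_ids or {})
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent, relation in edges:
            if child not in self.terms or parent not in self.terms:
                continue
            g.add_edge(child, parent, relation=relation)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(
                f"cycle among retained relations involving term {cycle[0][0]!r}"
            )
        self._g = g
        # Drop terms with no path to a root: roots are terms with no parents.
        self.roots: FrozenSet[str] = frozenset(
            t for t in g.nodes if g.out_degree(t) == 0
        )
        self._depths = self._compute_depths()
        unreachable = [t for t in self.terms if t not in self._depths]
        if unreachable:  # pragma: no cover - defensive; DAG terms always reach a sink
            logger.warning("dropping %d terms with no path to a root", len(unreachable))
            for t in unreachable:
                g.remove_node(t)
                del self.terms[t]
        self._leaf_cache: Dict[str, FrozenSet[str]] | None = None

    # -- basic protocol -----------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map an alternate id to its canonical id (identity otherwise)."""
        return self.alt_ids.get(term_id, term_id)

    def name_of(self, term_id: str) -> str:
        return self.terms[self._check(term_id)].name

    def edges(self) -> Iterable[Tuple[str, str, str]]:
        for child, parent, data in self._g.edges(data=True):
            yield child, parent, data["relation"]

    def _check(self, term_id: str) -> str:
        term_id = self.resolve(term_id)
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        return term_id

    # -- structural queries -------------------------------------------------

    def ancestors(self, term_id: str) -> Set[str]:
        """Transitive parents of ``term_id`` over the retained relations."""
        return set(nx.descendants(self._g, self._check(term_id)))

    def descendants(self, term_id: str) -> Set[str]:
        """Transitive children of ``term_id`` (excluding the term itself)."""
        return set(nx.ancestors(self._g, self._check(term_id)))

    def parents(self, term_id: str) -> Set[str]:
        return set(self._g.successors(self._check(term_id)))

    def children(self, term_id: str) -> Set[str]:
        return set(self._g.predecessors(self._check(term_id)))

    def depth(self, term_id: str) -> int:
        """Longest-path distance from a root; roots have depth 0."""
        return self._depths[self._check(term_id)]

    def is_leaf(self, term_id: str) -> bool:
        return self._g.in_degree(self._check(term_id)) == 0

    def leaves(self) -> FrozenSet[str]:
        """All leaves of the ontology (terms with no descendants)."""
        return frozenset(t for t in self._g.nodes if self._g.in_degree(t) == 0)

    def leaves_under(self, term_id: str) -> Set[str]:
        """Leaf descendants of ``term_id``; empty if the term is itself a leaf."""
        term_id = self._check(term_id)
        if self._leaf_cache is None:
            self._leaf_cache = self._compute_leaf_sets()
        return set(self._leaf_cache[term_id])

    def covering_candidates(
        self,
        initial_terms: Iterable[str],
        min_depth: int,
        blocklist: Iterable[str] = (),
    ) -> Dict[str, FrozenSet[str]]:
        """Candidate grouping terms for a set of annotated terms.

        A candidate *covers* an initial term when it is that term or one of
        its ancestors.  Candidates are the initial terms themselves (each
        covers itself, regardless of depth — a term with no useful shared
        ancestor stands for itself) plus every ancestor at depth at least
        ``min_depth``; blocklisted terms are never candidates.

        Returns a map from candidate id to the frozen subset of initial
        terms it covers.
        """
        initial = [self._check(t) for t in initial_terms]
        if not initial:
            raise ValueError("initial term set must be non-empty")
        blocked = {self.resolve(t) for t in blocklist}
        initial_set = set(initial)
        covers: Dict[str, Set[str]] = {}
        for i in initial:
            if i not in blocked:
                covers.setdefault(i, set()).add(i)
            for anc in self.ancestors(i):
                if anc in blocked:
                    continue
                if anc in initial_set or self._depths[anc] >= min_depth:
                    covers.setdefault(anc, set()).add(i)
        return {c: frozenset(s) for c, s in covers.items()}

    # -- internals ----------------------------------------------------------

    def _compute_depths(self) -> Dict[str, int]:
        depths: Dict[str, int] = {}
        # Edges run child→parent, so reverse topological order visits
        # parents first.
        for t in reversed(list(nx.topological_sort(self._g))):
            parent_depths = [depths[p] for p in self._g.successors(t)]
            depths[t] = max(parent_depths) + 1 if parent_depths else 0
        return depths

    def _compute_leaf_sets(self) -> Dict[str, FrozenSet[str]]:
        sets: Dict[str, FrozenSet[str]] = {}
        for t in nx.topological_sort(self._g):  # children before parents
            kids = list(self._g.predecessors(t))
            if not kids:
                sets[t] = frozenset()
            else:
                acc: Set[str] = set()
                for k in kids:
                    acc |= sets[k] if sets[k] else {k}
                sets[t] = frozenset(acc)
        return sets

    # -- I/O ----------------------------------------------------------------

    def to_edge_list(self, path: str) -> None:
        """Write a debugging edge list: term_id <TAB> parent_id <TAB> relation."""
        with open(path, "w") as fh:
            for child, parent, relation in sorted(self.edges()):
                fh.write(f"{child}\t{parent}\t{relation}\n")


def load_obo(
    path: str,
    allowed_relations: Iterable[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Load an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Only edges whose relation is in ``allowed_relations`` (default ``is_a``
    and ``part_of``) are retained.  Obsolete terms are excluded; ``alt_id``
    entries are recorded so annotations to merged ids resolve to canonical
    terms.  A cycle among the retained relations raises :class:`CycleError`.
    """
    allowed = frozenset(allowed_relations)
    try:
        raw = obonet.read_obo(path, ignore_obsolete=True)
    except OSError as exc:
        raise OntologyError(f"cannot read OBO file {path!r}: {exc}") from exc
    terms: Dict[str, OntologyTerm] = {}
    alt_ids: Dict[str, str] = {}
    edges = []
    for term_id, data in raw.nodes(data=True):
        synonyms = tuple(
            m.group(1)
            for s in data.get("synonym", ())
            if (m := _SYNONYM_RE.search(s))
        )
        terms[term_id] = OntologyTerm(
            term_id=term_id,
            name=data.get("name", term_id),
            synonyms=synonyms,
        )
        for alt in data.get("alt_id", ()):
            alt_ids[alt] = term_id
    for child, parent, relation in raw.edges(keys=True):
        if relation in allowed:
            edges.append((child, parent, relation))
    name = raw.graph.get("ontology", "") if hasattr(raw, "graph") else ""
    return OntologyGraph(terms, edges, alt_ids=alt_ids, name=name)
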