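"""Ontology loading and DAG-query tests, checked against brute-force
oracles that traverse the raw edge lists directly."""

import textwrap

import networkx as nx
import pytest

from genesum.fixtures import FixtureSpec, random_dag, to_obo
from genesum.ontology import (
    CycleError,
    OntologyGraph,
    OntologyTerm,
    UnknownTermError,
    load_obo,
)

from conftest import make_graph, small_random_graphs

TOY_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: toy

    [Term]
    id: T:0001
    name: root

    [Term]
    id: T:0002
    name: a
    alt_id: T:0099
    synonym: "alpha" EXACT []
    is_a: T:0001

    [Term]
    id: T:0003
    name: b
    relationship: part_of T:0002
    relationship: regulates T:0001

    [Term]
    id: T:0004
    name: gone
    is_obsolete: true
    is_a: T:0001
    """
)


# ---------------------------------------------------------------------------
# Loading


class TestLoadObo:
    @pytest.fixture
    def graph(self, tmp_path):
        path = tmp_path / "toy.obo"
        path.write_text(TOY_OBO)
        return load_obo(str(path))

    def test_parses_terms_and_retained_edges(self, graph):
        assert set(graph.terms) == {"T:0001", "T:0002", "T:0003"}
        assert set(graph.edges()) == {
            ("T:0002", "T:0001", "is_a"),
            ("T:0003", "T:0002", "part_of"),
        }

    def test_non_hierarchical_relations_are_dropped(self, graph):
        # the regulates edge T:0003 -> T:0001 must not create ancestry
        assert graph.ancestors("T:0003") == {"T:0002", "T:0001"}

    def test_obsolete_term_excluded(self, graph):
        assert "T:0004" not in graph
        with pytest.raises(UnknownTermError):
            graph.ancestors("T:0004")

    def test_alt_id_resolves_to_canonical(self, graph):
        assert graph.resolve("T:0099") == "T:0002"
        assert graph.ancestors("T:0099") == {"T:0001"}

    def test_synonyms_retained(self, graph):
        assert graph.terms["T:0002"].synonyms == ("alpha",)

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(Exception):
            load_obo(str(tmp_path / "missing.obo"))

    def test_cycle_raises_naming_a_member(self):
        edges = [("A", "B", "is_a"), ("B", "A", "is_a")]
        terms = {t: OntologyTerm(t, t) for t in "AB"}
        with pytest.raises(CycleError):
            OntologyGraph(terms, edges)


# ---------------------------------------------------------------------------
# Structural queries on hand graphs


class TestQueries:
    def test_chain_closures(self, chain):
        assert chain.ancestors("B") == {"A", "R"}
        assert chain.ancestors("R") == set()
        assert chain.descendants("R") == {"A", "B"}
        assert chain.descendants("B") == set()
        assert chain.depth("B") == 2

    def test_diamond_closures(self, diamond):
        assert diamond.ancestors("Z") == {"X", "Y", "R"}
        assert diamond.descendants("R") == {"X", "Y", "Z"}

    def test_depth_is_longest_path(self):
        # X reachable directly from R and through W: depth is the longer path
        g = make_graph([("X", "R", "is_a"), ("W", "R", "is_a"), ("X", "W", "is_a")])
        assert g.depth("X") == 2

    def test_leaves_under(self):
        g = make_graph(
            [("A", "R", "is_a"), ("l1", "A", "is_a"), ("l2", "A", "is_a")]
        )
        assert g.leaves_under("A") == {"l1", "l2"}
        assert g.leaves_under("l1") == set()  # a leaf has no leaf descendants
        assert g.leaves_under("R") == {"l1", "l2"}

    def test_unknown_term_raises(self, chain):
        for fn in (chain.ancestors, chain.descendants, chain.depth, chain.leaves_under):
            with pytest.raises(UnknownTermError):
                fn("nope")


# ---------------------------------------------------------------------------
# Covering candidates


class TestCoveringCandidates:
    def test_initial_term_covers_itself(self, chain):
        cands = chain.covering_candidates({"B"}, min_depth=2)
        assert cands["B"] == frozenset({"B"})

    def test_shallow_ancestors_excluded(self, chain):
        # A (depth 1) and R (depth 0) fall below the floor
        cands = chain.covering_candidates({"B"}, min_depth=2)
        assert set(cands) == {"B"}

    def test_blocklisted_terms_never_candidates(self, chain):
        cands = chain.covering_candidates({"B"}, min_depth=0, blocklist={"A"})
        assert "A" not in cands
        assert cands["R"] == frozenset({"B"})

    def test_empty_initial_set_rejected(self, chain):
        with pytest.raises(ValueError):
            chain.covering_candidates(set(), min_depth=0)

    def test_matches_exhaustive_check_on_random_dags(self):
        import random

        rng = random.Random(42)
        for g in small_random_graphs(10, max_terms=40):
            ids = sorted(g.terms)
            initial = set(rng.sample(ids, min(5, len(ids))))
            min_depth = rng.randint(0, 3)
            cands = g.covering_candidates(initial, min_depth)
            # oracle: test every (term, initial) pair directly
            for t in ids:
                covered = frozenset(
                    i for i in initial if t == i or t in g.ancestors(i)
                )
                eligible = covered and (t in initial or g.depth(t) >= min_depth)
                if t in initial:
                    assert cands[t] == covered
                elif eligible:
                    assert cands.get(t) == covered
                else:
                    assert t not in cands or t in initial


# ---------------------------------------------------------------------------
# Oracle agreement and invariants on random DAGs


def _closure_oracle(graph):
    """Transitive closure computed from the raw edge list, not the graph API."""
    parents = {}
    for child, parent, _ in graph.edges():
        parents.setdefault(child, set()).add(parent)
    up = {}

    def climb(t):
        if t not in up:
            acc = set()
            for p in parents.get(t, ()):
                acc.add(p)
                acc |= climb(p)
            up[t] = acc
        return up[t]

    return {t: climb(t) for t in graph.terms}


def test_random_dags_agree_with_brute_force_oracles():
    for g in small_random_graphs(100, max_terms=60):
        up = _closure_oracle(g)
        down = {t: set() for t in g.terms}
        for t, anc in up.items():
            for a in anc:
                down[a].add(t)
        leaf_ids = {t for t in g.terms if not down[t]}
        for t in g.terms:
            assert g.ancestors(t) == up[t]
            assert g.descendants(t) == down[t]
            assert g.leaves_under(t) == down[t] & leaf_ids
        # inverse property
        for t in g.terms:
            for a in g.ancestors(t):
                assert t in g.descendants(a)
        # depth consistency along every retained edge
        for child, parent, _ in g.edges():
            assert g.depth(child) >= g.depth(parent) + 1


def test_depth_equals_exhaustive_path_enumeration():
    """On small DAGs, depth must equal the longest root-to-term path found
    by enumerating every simple path."""
    for g in small_random_graphs(20, max_terms=20, seed0=300):
        raw = nx.DiGraph((c, p) for c, p, _ in g.edges())
        raw.add_nodes_from(g.terms)
        for t in g.terms:
            best = 0
            for root in g.roots:
                for path in nx.all_simple_paths(raw, t, root):
                    best = max(best, len(path) - 1)
            assert g.depth(t) == best


def test_obo_round_trip_preserves_structure():
    spec = FixtureSpec(n_terms=40, seed=5)
    g = random_dag(spec)
    text = to_obo(g)
    import io, tempfile, os

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "x.obo")
        with open(path, "w") as fh:
            fh.write(text)
        g2 = load_obo(path)
    assert set(g2.terms) == set(g.terms)
    assert set(g2.edges()) == set(g.edges())
    assert all(g2.terms[t].name == g.terms[t].name for t in g.terms)
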