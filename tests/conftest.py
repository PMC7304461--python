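import pytest

from genesum.fixtures import FixtureSpec, random_dag
from genesum.ontology import OntologyGraph, OntologyTerm


def make_graph(edges, extra_terms=()):
    """Build a graph from (child, parent, relation) triples."""
    ids = {t for e in edges for t in e[:2]} | set(extra_terms)
    terms = {t: OntologyTerm(term_id=t, name=f"name of {t}") for t in ids}
    return OntologyGraph(terms, edges)


@pytest.fixture
def chain():
    """R <- A <- B."""
    return make_graph([("A", "R", "is_a"), ("B", "A", "is_a")])


@pytest.fixture
def diamond():
    """R <- X <- Z and R <- Y <- Z."""
    return make_graph(
        [
            ("X", "R", "is_a"),
            ("Y", "R", "is_a"),
            ("Z", "X", "is_a"),
            ("Z", "Y", "part_of"),
        ]
    )


def small_random_graphs(n_graphs, max_terms=60, seed0=100):
    for i in range(n_graphs):
        spec = FixtureSpec(
            n_terms=10 + (i * 7) % (max_terms - 9), max_parents=3, seed=seed0 + i
        )
        yield random_dag(spec)
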