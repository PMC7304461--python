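"""Synthetic ontologies, annotation sets, corpora and ortholog tables.

Everything the pipeline consumes can be generated here from a seeded
specification, so the full workflow — OBO loading, GAF parsing, evidence
prioritization, trimming, rendering and evaluation — runs and is testable
without downloading any real ontology or annotation release.  The
generated ontologies are rooted DAGs built in topological order (hence
acyclic by construction) and are emitted as OBO 1.2 text that round-trips
through :func:`genesum.ontology.load_obo`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Tuple

import numpy as np

from genesum.ontology import OntologyGraph, OntologyTerm

# Evidence codes per tier, used when sampling annotation evidence.
TIER_CODES: Mapping[str, Tuple[str, ...]] = {
    "experimental": ("EXP", "IDA", "IPI", "IMP", "IGI", "IEP"),
    "high_throughput": ("HTP", "HDA", "HMP", "HGI", "HEP"),
    "phylogenetic": ("IBA", "IBD", "IKR", "IRD"),
    "curator_author": ("IC", "TAS", "NAS"),
    "computational": ("ISS", "ISO", "ISA", "ISM", "IGC", "RCA"),
    "electronic": ("IEA",),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture.

    Defaults emulate a mid-sized model-organism setting: ontologies of a
    few hundred terms with mostly ``is_a`` edges and occasional multiple
    parentage, genes carrying a handful to a few dozen annotations (so a
    realistic fraction of genes exceeds the per-category term caps and
    exercises trimming), evidence dominated by experimental and electronic
    codes, and rare NOT/qualifier flags.
    """

    n_terms: int = 150
    max_parents: int = 3
    part_of_ratio: float = 0.2
    n_genes: int = 500
    mean_terms_per_gene: float = 8.0
    tier_mix: Tuple[Tuple[str, float], ...] = (
        ("experimental", 0.35),
        ("high_throughput", 0.10),
        ("phylogenetic", 0.08),
        ("curator_author", 0.07),
        ("computational", 0.15),
        ("electronic", 0.25),
    )
    qualifier_prob: float = 0.05
    not_prob: float = 0.03
    seed: int = 0
    prefix: str = "TOY"


# ---------------------------------------------------------------------------
# Ontology generation


def random_dag(spec: FixtureSpec) -> OntologyGraph:
    """Build a connected, single-root random DAG.

    Terms are created in topological order; each non-root term picks one
    to ``max_parents`` parents among earlier terms with a bias toward
    recent terms, which yields deep, branchy graphs like real ontologies.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"{spec.prefix}:{i + 1:07d}" for i in range(spec.n_terms)]
    terms: Dict[str, OntologyTerm] = {}
    edges: List[Tuple[str, str, str]] = []
    for i, term_id in enumerate(ids):
        synonyms: Tuple[str, ...] = ()
        if i and rng.random() < 0.3:
            synonyms = (f"syn {spec.prefix.lower()} {i + 1}",)
        terms[term_id] = OntologyTerm(
            term_id=term_id,
            name=f"{spec.prefix.lower()} term {i + 1}",
            synonyms=synonyms,
        )
        if i == 0:
            continue
        n_parents = 1 + int(rng.integers(0, spec.max_parents)) if i > 1 else 1
        n_parents = min(n_parents, i)
        # Mild recency bias: deepens the graph to ontology-like levels
        # (max depth ~15 at 150 terms) without degenerating into chains.
        weights = np.arange(1, i + 1, dtype=float) ** 0.5
        weights /= weights.sum()
        parents = rng.choice(i, size=n_parents, replace=False, p=weights)
        for p in sorted(parents):
            relation = "part_of" if rng.random() < spec.part_of_ratio else "is_a"
            edges.append((term_id, ids[int(p)], relation))
    return OntologyGraph(terms, edges, name=spec.prefix.lower())


def to_obo(graph: OntologyGraph) -> str:
    """Serialize a graph to OBO 1.2 text (round-trippable via load_obo)."""
    lines = ["format-version: 1.2", f"ontology: {graph.name or 'toy'}", ""]
    by_parent: Dict[str, List[Tuple[str, str]]] = {}
    for child, parent, relation in graph.edges():
        by_parent.setdefault(child, []).append((relation, parent))
    for term_id in sorted(graph.terms):
        term = graph.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {term.name}")
        for syn in term.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for relation, parent in sorted(by_parent.get(term_id, [])):
            if relation == "is_a":
                lines.append(f"is_a: {parent} ! {graph.terms[parent].name}")
            else:
                lines.append(
                    f"relationship: {relation} {parent} ! {graph.terms[parent].name}"
                )
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Annotation generation


def _sample_terms(graph: OntologyGraph, rng: np.random.Generator, k: int) -> List[str]:
    # Annotate preferentially to deeper (more specific) terms, as curators do.
    ids = sorted(graph.terms)
    depths = np.array([graph.depth(t) for t in ids], dtype=float)
    weights = (depths + 1.0) ** 2
    weights /= weights.sum()
    k = min(k, len(ids))
    picks = rng.choice(len(ids), size=k, replace=False, p=weights)
    return [ids[int(i)] for i in sorted(picks)]


def _sample_evidence(spec: FixtureSpec, rng: np.random.Generator) -> str:
    names = [n for n, _ in spec.tier_mix]
    probs = np.array([p for _, p in spec.tier_mix], dtype=float)
    probs /= probs.sum()
    tier = names[int(rng.choice(len(names), p=probs))]
    codes = TIER_CODES[tier]
    return codes[int(rng.integers(0, len(codes)))]


def random_gene_terms(
    graph: OntologyGraph, spec: FixtureSpec
) -> Dict[str, List[str]]:
    """Sample each gene's annotated term list (the benchmark substrate)."""
    rng = np.random.default_rng(spec.seed + 1)
    genes: Dict[str, List[str]] = {}
    for g in range(spec.n_genes):
        gene_id = f"GENE:{g + 1:05d}"
        k = 1 + int(rng.poisson(max(spec.mean_terms_per_gene - 1.0, 0.0)))
        genes[gene_id] = _sample_terms(graph, rng, k)
    return genes


def random_annotations(graph: OntologyGraph, spec: FixtureSpec) -> Dict[str, str]:
    """Generate annotation files against ``graph``.

    Returns text blobs keyed by filename: a GAF 2.2 file (GO-style, with
    sampled evidence codes, occasional qualifiers and NOT flags), a
    disease association TSV, an expression TSV, an ortholog TSV and a
    corpus-frequency TSV.
    """
    rng = np.random.default_rng(spec.seed + 2)
    gene_terms = random_gene_terms(graph, spec)

    gaf_lines = ["!gaf-version: 2.2"]
    disease_lines: List[str] = []
    expr_lines: List[str] = []
    aspects = ("F", "P", "C")
    for gene_id, terms in gene_terms.items():
        symbol = f"gene-{gene_id.split(':')[1]}"
        for term in terms:
            evidence = _sample_evidence(spec, rng)
            quals: List[str] = []
            if rng.random() < spec.not_prob:
                quals.append("NOT")
            if rng.random() < spec.qualifier_prob:
                quals.append("contributes_to")
            aspect = aspects[int(rng.integers(0, 3))]
            db, db_id = gene_id.split(":", 1)
            gaf_lines.append(
                "\t".join(
                    [
                        db,
                        db_id,
                        symbol,
                        "|".join(quals),
                        term,
                        "REF:0000001",
                        evidence,
                        "",
                        aspect,
                        symbol,
                        "",
                        "gene",
                        "taxon:0000",
                        "20200101",
                        "TOY",
                    ]
                )
            )
        if terms and rng.random() < 0.3:
            assoc = ("is_model_of", "is_marker_of", "is_implicated_in")[
                int(rng.integers(0, 3))
            ]
            disease_lines.append(
                f"{gene_id}\t{terms[0]}\t{assoc}\t{_sample_evidence(spec, rng)}\t{symbol}"
            )
        if terms and rng.random() < 0.5:
            for term in terms[: int(rng.integers(1, 4))]:
                expr_lines.append(
                    f"{gene_id}\t{term}\texpressed_in\tIDA\t{symbol}"
                )

    ortho_lines: List[str] = []
    human_symbols = [f"HG{i}" for i in range(1, 40)]
    for gene_id in gene_terms:
        n = int(rng.integers(0, 4))
        chosen = rng.choice(len(human_symbols), size=n, replace=False)
        for c in chosen:
            sym = human_symbols[int(c)]
            ortho_lines.append(
                f"{gene_id}\t{sym}\thuman gene {sym}\tHomo sapiens\t"
                f"{int(rng.integers(1, 11))}\ttrue"
            )

    # Corpus term frequencies: shallow (general) terms appear more often.
    corpus_lines = []
    for term_id in sorted(graph.terms):
        m = int(rng.poisson(200.0 * 0.6 ** graph.depth(term_id)))
        corpus_lines.append(f"{term_id}\t{m}")

    return {
        "annotations.gaf": "\n".join(gaf_lines) + "\n",
        "disease.tsv": "\n".join(disease_lines) + ("\n" if disease_lines else ""),
        "expression.tsv": "\n".join(expr_lines) + ("\n" if expr_lines else ""),
        "orthologs.tsv": "\n".join(ortho_lines) + ("\n" if ortho_lines else ""),
        "corpus_counts.tsv": "\n".join(corpus_lines) + "\n",
    }


def write_fixtures(spec: FixtureSpec, out_dir: str) -> Dict[str, str]:
    """Write a complete fixture set (ontology OBO + annotation files).

    Returns a map from logical name to written path.
    """
    os.makedirs(out_dir, exist_ok=True)
    graph = random_dag(spec)
    paths: Dict[str, str] = {}
    obo_path = os.path.join(out_dir, f"{spec.prefix.lower()}.obo")
    with open(obo_path, "w") as fh:
        fh.write(to_obo(graph))
    paths["ontology"] = obo_path
    for name, text in random_annotations(graph, spec).items():
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fh.write(text)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Hand-built anatomy-style fixture


def fig3_like_fixture() -> Tuple[OntologyGraph, FrozenSet[str], FrozenSet[str]]:
    """An anatomy-style DAG with two hub ancestors.

    Five annotated cell-level terms fall in two clusters whose only
    shared ancestors at depth ≥ 3 are "pharynx" and "neuron"; LCA-based
    trimming with min_depth=3 must select exactly those two hubs.

    Returns ``(graph, initial_terms, expected_selection)``.
    """
    names = {
        "AO:0000001": "whole organism",
        "AO:0000002": "organ system",
        "AO:0000003": "alimentary system",
        "AO:0000004": "cell",
        "AO:0000005": "excitable cell",
        "AO:0000006": "pharynx",
        "AO:0000007": "neuron",
        "AO:0000008": "pharyngeal muscle cell",
        "AO:0000009": "pharyngeal gland cell",
        "AO:0000010": "pharyngeal epithelial cell",
        "AO:0000011": "motor neuron",
        "AO:0000012": "sensory neuron",
    }
    edges = [
        ("AO:0000002", "AO:0000001", "is_a"),
        ("AO:0000003", "AO:0000002", "is_a"),
        ("AO:0000004", "AO:0000001", "is_a"),
        ("AO:0000005", "AO:0000004", "is_a"),
        ("AO:0000006", "AO:0000003", "part_of"),
        ("AO:0000007", "AO:0000005", "is_a"),
        ("AO:0000008", "AO:0000006", "part_of"),
        ("AO:0000009", "AO:0000006", "part_of"),
        ("AO:0000010", "AO:0000006", "part_of"),
        ("AO:0000011", "AO:0000007", "is_a"),
        ("AO:0000012", "AO:0000007", "is_a"),
    ]
    terms = {tid: OntologyTerm(term_id=tid, name=n) for tid, n in names.items()}
    graph = OntologyGraph(terms, edges, name="toy anatomy")
    initial = frozenset(
        {"AO:0000008", "AO:0000009", "AO:0000010", "AO:0000011", "AO:0000012"}
    )
    expected = frozenset({"AO:0000006", "AO:0000007"})
    return graph, initial, expected
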