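"""Comparison statistics for trimming algorithms.

For each algorithm (LCA, IC-Sánchez-weighted, IC-annotation-weighted) the
benchmark reports, averaged over genes: the percentage of the initial
annotated terms covered by the selected grouping terms, the mean ontology
depth of the selected terms, and their mean corpus IC.  Specificity gains
are summarized against the LCA baseline as

    gain_X = 100·(X_alg − X_lca)/X_lca − 100·(cov_lca − cov_alg)/cov_lca

for X ∈ {depth, corpus IC}: the relative percentage gain in specificity
minus the relative percentage loss in coverage.  Gains are 0 by definition
for the LCA row.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from genesum.annotations import CategoryConfig
from genesum.information_content import (
    AnnotationCorpus,
    CorpusFrequencies,
    ic_annot_table,
    ic_corpus,
    ic_sanchez_table,
)
from genesum.ontology import OntologyGraph
from genesum.trimming import TrimResult, trim_ic, trim_lca

ALGORITHMS = ("lca", "ic_sanchez", "ic_annot")


@dataclass
class AlgorithmStats:
    """One row of the algorithm-comparison table."""

    algorithm: str
    avg_coverage: float  # percent
    avg_depth: float
    avg_ic_corpus: float
    coverage_depth_gain_wrt_lca: float  # percent
    coverage_ic_gain_wrt_lca: float  # percent
    n_genes: int


def gene_metrics(
    initial: Set[str],
    result: TrimResult,
    graph: OntologyGraph,
    freqs: CorpusFrequencies,
) -> Tuple[float, float, float]:
    """Per-gene metrics of a trim: (coverage %, mean selected depth,
    mean selected corpus IC)."""
    if not initial:
        raise ValueError("initial term set must be non-empty")
    covered = result.covered & initial
    coverage = 100.0 * len(covered) / len(initial)
    if result.selected:
        depth = mean(graph.depth(t) for t in result.selected)
        ic = mean(ic_corpus(t, freqs) for t in result.selected)
    else:
        depth = 0.0
        ic = 0.0
    return coverage, depth, ic


def _run_algorithm(
    algorithm: str,
    genes: Mapping[str, Set[str]],
    graph: OntologyGraph,
    config: CategoryConfig,
    ic_tables: Mapping[str, Mapping[str, float]],
) -> Dict[str, TrimResult]:
    results: Dict[str, TrimResult] = {}
    for gene_id, initial in genes.items():
        if algorithm == "lca":
            results[gene_id] = trim_lca(initial, graph, config)
        else:
            results[gene_id] = trim_ic(initial, graph, ic_tables[algorithm], config)
    return results


def compare_algorithms(
    genes: Mapping[str, Set[str]],
    graph: OntologyGraph,
    freqs: CorpusFrequencies,
    config: CategoryConfig,
    annotation_corpus: AnnotationCorpus | None = None,
    algorithms: Sequence[str] = ALGORITHMS,
) -> List[AlgorithmStats]:
    """Trim every gene's term set with each algorithm and tabulate.

    ``genes`` maps gene id → initial (pruned) annotated term set.  The
    annotation corpus behind the IC-annot weights defaults to the genes'
    own annotations.
    """
    if annotation_corpus is None:
        annotation_corpus = AnnotationCorpus(
            {g: set(ts) for g, ts in genes.items()}
        )
    ic_tables: Dict[str, Mapping[str, float]] = {}
    if "ic_sanchez" in algorithms:
        ic_tables["ic_sanchez"] = ic_sanchez_table(graph)
    if "ic_annot" in algorithms:
        ic_tables["ic_annot"] = ic_annot_table(graph, annotation_corpus)

    per_alg: Dict[str, Tuple[float, float, float]] = {}
    for alg in algorithms:
        results = _run_algorithm(alg, genes, graph, config, ic_tables)
        metrics = [
            gene_metrics(initial, results[g], graph, freqs)
            for g, initial in genes.items()
        ]
        cov = mean(m[0] for m in metrics)
        depth = mean(m[1] for m in metrics)
        ic = mean(m[2] for m in metrics)
        per_alg[alg] = (cov, depth, ic)

    rows: List[AlgorithmStats] = []
    base = per_alg.get("lca")
    for alg in algorithms:
        cov, depth, ic = per_alg[alg]
        if base is None or alg == "lca":
            gain_depth = gain_ic = 0.0
        else:
            cov_lca, depth_lca, ic_lca = base
            cov_loss = 100.0 * (cov_lca - cov) / cov_lca if cov_lca else 0.0
            gain_depth = (
                100.0 * (depth - depth_lca) / depth_lca if depth_lca else 0.0
            ) - cov_loss
            gain_ic = (100.0 * (ic - ic_lca) / ic_lca if ic_lca else 0.0) - cov_loss
        rows.append(
            AlgorithmStats(
                algorithm=alg,
                avg_coverage=cov,
                avg_depth=depth,
                avg_ic_corpus=ic,
                coverage_depth_gain_wrt_lca=gain_depth,
                coverage_ic_gain_wrt_lca=gain_ic,
                n_genes=len(genes),
            )
        )
    return rows


def stats_to_tsv(rows: Sequence[AlgorithmStats], path: str) -> None:
    """Write the comparison table (one row per algorithm)."""
    header = (
        "algorithm\tavg_coverage\tavg_depth\tavg_ic_corpus\t"
        "coverage_depth_gain_wrt_lca\tcoverage_ic_gain_wrt_lca\tn_genes\n"
    )
    with open(path, "w") as fh:
        fh.write("# gain_X = 100*(X_alg-X_lca)/X_lca - 100*(cov_lca-cov_alg)/cov_lca\n")
        fh.write(header)
        for r in rows:
            fh.write(
                f"{r.algorithm}\t{r.avg_coverage:.2f}\t{r.avg_depth:.3f}\t"
                f"{r.avg_ic_corpus:.3f}\t{r.coverage_depth_gain_wrt_lca:.2f}\t"
                f"{r.coverage_ic_gain_wrt_lca:.2f}\t{r.n_genes}\n"
            )
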