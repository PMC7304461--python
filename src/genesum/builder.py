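"""Per-gene summary assembly and output writing.

The pipeline per data category is: evidence prioritization → blocklist /
do-not-annotate filtering → parent/child redundancy pruning → trimming
(only when the term list exceeds the category's ``max_terms``) → template
rendering.  The orthology sentence is appended and all sentences are
concatenated in a fixed category order.  Processing is per-gene and
deterministic: identical inputs always produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from genesum.annotations import (
    CategoryConfig,
    EvidencePolicy,
    GeneAnnotation,
    default_configs,
    filter_terms,
    prioritize_by_evidence,
    prune_redundant,
)
from genesum.information_content import (
    AnnotationCorpus,
    ic_annot_table,
    ic_sanchez_table,
)
from genesum.ontology import OntologyGraph
from genesum.orthology import (
    OrthologRecord,
    render_orthology_sentence,
    select_best_orthologs,
)
from genesum.sentences import (
    CATEGORY_ORDER,
    SentenceTemplate,
    assemble_summary,
    default_templates,
    render_sentence,
)
from genesum.trimming import TrimResult, trim_ic, trim_lca, trim_naive

logger = logging.getLogger(__name__)


@dataclass
class CategorySentence:
    """One rendered sentence plus the terms behind it."""

    category: str
    sentence: str
    term_ids: List[str]
    predicted: bool = False
    trimmed: bool = False
    qualifier: Optional[str] = None


@dataclass
class GeneSummary:
    """The assembled summary for one gene."""

    gene_id: str
    gene_symbol: str = ""
    text: str = ""
    sentences: List[CategorySentence] = field(default_factory=list)


class SummaryPipeline:
    """Builds summaries for a cohort of genes.

    Parameters
    ----------
    graphs
        Ontologies keyed by the name each :class:`CategoryConfig` refers
        to (e.g. ``"go"``, ``"do"``, ``"anatomy"``).
    annotations
        All gene annotations for the cohort; the full set is also the
        annotation corpus behind the annotation-frequency IC weights.
    orthologs
        Stringent human-ortholog records for all genes.
    configs / templates / policy
        Per-category policy; defaults cover the standard seven categories.
    algorithm
        Optional override of every category's trimming algorithm
        (``lca``, ``ic_sanchez``, ``ic_annot`` or ``naive``).
    """

    def __init__(
        self,
        graphs: Mapping[str, OntologyGraph],
        annotations: Sequence[GeneAnnotation] = (),
        orthologs: Sequence[OrthologRecord] = (),
        configs: Mapping[str, CategoryConfig] | None = None,
        templates: Mapping[str, SentenceTemplate] | None = None,
        policy: EvidencePolicy | None = None,
        algorithm: Optional[str] = None,
    ) -> None:
        self.graphs = dict(graphs)
        self.annotations = list(annotations)
        self.orthologs = list(orthologs)
        self.configs = dict(configs) if configs is not None else default_configs()
        self.templates = dict(templates) if templates is not None else default_templates()
        self.policy = policy or EvidencePolicy()
        self.algorithm = algorithm
        self._ic_cache: Dict[Tuple[str, str], Mapping[str, float]] = {}

    # -- IC weights ---------------------------------------------------------

    def _ic_table(self, ontology: str, measure: str) -> Mapping[str, float]:
        key = (ontology, measure)
        if key not in self._ic_cache:
            graph = self.graphs[ontology]
            if measure == "ic_sanchez":
                self._ic_cache[key] = ic_sanchez_table(graph)
            elif measure == "ic_annot":
                corpus = self._annotation_corpus(ontology)
                self._ic_cache[key] = ic_annot_table(graph, corpus)
            else:
                raise ValueError(f"unknown IC measure {measure!r}")
        return self._ic_cache[key]

    def _annotation_corpus(self, ontology: str) -> AnnotationCorpus:
        graph = self.graphs[ontology]
        categories = {c.name for c in self.configs.values() if c.ontology == ontology}
        gene_to_terms: Dict[str, set] = {}
        for a in self.annotations:
            if a.negated or a.category not in categories:
                continue
            term = graph.resolve(a.term_id)
            if term in graph:
                gene_to_terms.setdefault(a.gene_id, set()).add(term)
        return AnnotationCorpus(gene_to_terms)

    # -- trimming -----------------------------------------------------------

    def _trim(
        self, terms: set, graph: OntologyGraph, config: CategoryConfig
    ) -> TrimResult:
        algorithm = self.algorithm or config.trim_algorithm
        if algorithm == "lca":
            return trim_lca(terms, graph, config)
        if algorithm in {"ic_sanchez", "ic_annot"}:
            table = self._ic_table(config.ontology, algorithm)
            return trim_ic(terms, graph, table, config)
        if algorithm == "naive":
            return trim_naive(terms, graph, config)
        raise ValueError(f"unknown trimming algorithm {algorithm!r}")

    # -- per-gene assembly --------------------------------------------------

    def summary_for(self, gene_id: str, gene_symbol: str = "") -> GeneSummary:
        gene_anns = [
            a for a in self.annotations if a.gene_id == gene_id and not a.negated
        ]
        if not gene_symbol:
            symbols = [a.gene_symbol for a in gene_anns if a.gene_symbol]
            gene_symbol = symbols[0] if symbols else ""
        sentences: List[CategorySentence] = []
        for category in CATEGORY_ORDER:
            if category == "orthology":
                sentences.extend(self._orthology_sentence(gene_id))
                continue
            config = self.configs.get(category)
            if config is None:
                continue
            sentences.extend(self._category_sentences(gene_anns, category, config))
        text = assemble_summary([s.sentence for s in sentences])
        return GeneSummary(
            gene_id=gene_id, gene_symbol=gene_symbol, text=text, sentences=sentences
        )

    def _category_sentences(
        self,
        gene_anns: Sequence[GeneAnnotation],
        category: str,
        config: CategoryConfig,
    ) -> List[CategorySentence]:
        graph = self.graphs.get(config.ontology)
        if graph is None:
            return []
        template = self.templates.get(category)
        anns = [a for a in gene_anns if a.category == category]
        anns = [a for a in anns if graph.resolve(a.term_id) in graph]
        if not anns or template is None:
            return []
        anns = prioritize_by_evidence(anns, self.policy)
        predicted = self.policy.is_predicted(anns[0].evidence_code)
        anns = filter_terms(anns, config, graph)
        if not anns:
            return []
        # Qualified annotations (contributes_to, colocalizes_with) are
        # rendered as their own sentence after the plain one.
        groups: List[Tuple[Optional[str], List[GeneAnnotation]]] = [(None, [])]
        special = set(template.qualifier_phrases)
        for q in sorted(special):
            groups.append((q, []))
        for a in anns:
            hit = next((q for q in a.qualifiers if q in special), None)
            next(g for k, g in groups if k == hit).append(a)
        out: List[CategorySentence] = []
        for qualifier, group in groups:
            if not group:
                continue
            terms = prune_redundant(
                {a.term_id for a in group}, graph, config.prune_direction
            )
            if len(terms) > config.max_terms:
                result = self._trim(terms, graph, config)
            else:
                selected = sorted(terms)
                result = TrimResult(
                    selected=selected,
                    covers={t: frozenset({t}) for t in selected},
                    coverage=1.0,
                    trimmed=False,
                    multiple_flags={t: False for t in selected},
                )
            names = [graph.name_of(t) for t in result.selected]
            sentence = render_sentence(
                template,
                names,
                trimmed=result.trimmed,
                predicted=predicted,
                qualifier=qualifier,
                multiple_flags=[result.multiple_flags.get(t, False) for t in result.selected],
            )
            out.append(
                CategorySentence(
                    category=category,
                    sentence=sentence,
                    term_ids=list(result.selected),
                    predicted=predicted,
                    trimmed=result.trimmed,
                    qualifier=qualifier,
                )
            )
        return out

    def _orthology_sentence(self, gene_id: str) -> List[CategorySentence]:
        records = [r for r in self.orthologs if r.gene_id == gene_id]
        selected, truncated = select_best_orthologs(records)
        sentence = render_orthology_sentence(selected, truncated)
        if not sentence:
            return []
        return [
            CategorySentence(
                category="orthology",
                sentence=sentence,
                term_ids=[r.ortholog_symbol for r in selected],
                trimmed=truncated,
            )
        ]

    def run(self, gene_ids: Iterable[str] | None = None) -> List[GeneSummary]:
        """Build summaries for every gene (sorted by gene id)."""
        if gene_ids is None:
            ids = {a.gene_id for a in self.annotations}
            ids |= {r.gene_id for r in self.orthologs}
            gene_ids = ids
        return [self.summary_for(g) for g in sorted(gene_ids)]


def build_summary(
    gene_id: str,
    graphs: Mapping[str, OntologyGraph],
    annotations: Sequence[GeneAnnotation],
    orthologs: Sequence[OrthologRecord] = (),
    configs: Mapping[str, CategoryConfig] | None = None,
    templates: Mapping[str, SentenceTemplate] | None = None,
    policy: EvidencePolicy | None = None,
    algorithm: Optional[str] = None,
) -> GeneSummary:
    """Build the summary of a single gene (convenience wrapper around
    :class:`SummaryPipeline`)."""
    pipeline = SummaryPipeline(
        graphs,
        annotations,
        orthologs,
        configs=configs,
        templates=templates,
        policy=policy,
        algorithm=algorithm,
    )
    return pipeline.summary_for(gene_id)


def write_outputs(
    summaries: Sequence[GeneSummary],
    out_dir: str,
    formats: Sequence[str] = ("json", "tsv"),
) -> List[str]:
    """Write summaries to ``out_dir`` as JSON and/or flat TSV.

    Output ordering is by gene id and serialization is canonical, so
    re-running on identical inputs yields byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    ordered = sorted(summaries, key=lambda s: s.gene_id)
    paths: List[str] = []
    if "json" in formats:
        payload = [
            {
                "gene_id": s.gene_id,
                "gene_symbol": s.gene_symbol,
                "description": s.text,
                "categories": [
                    {
                        "name": c.category,
                        "sentence": c.sentence,
                        "term_ids": c.term_ids,
                        "predicted": c.predicted,
                        "trimmed": c.trimmed,
                    }
                    for c in s.sentences
                ],
            }
            for s in ordered
        ]
        path = os.path.join(out_dir, "summaries.json")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths.append(path)
    if "tsv" in formats:
        path = os.path.join(out_dir, "summaries.tsv")
        with open(path, "w") as fh:
            for s in ordered:
                fh.write(f"{s.gene_id}\t{s.text}\n")
        paths.append(path)
    return paths
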