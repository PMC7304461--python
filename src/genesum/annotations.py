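"""Gene→term association handling.

Reads GAF 2.1/2.2 files and generic association TSVs, prioritizes
annotations by evidence tier (experimental evidence beats everything else;
a gene with only electronic evidence still gets a sentence, flagged as
predicted), applies blocklist / do-not-annotate filtering, and removes
parent/child redundancy before trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from genesum.ontology import OntologyGraph

logger = logging.getLogger(__name__)

FrozenSetStr = frozenset

# GAF column-7 aspect letters → data-category names.
ASPECT_TO_CATEGORY = {
    "F": "molecular_function",
    "P": "biological_process",
    "C": "cellular_component",
}

# Association types accepted in the generic disease/expression TSV.
ASSOCIATION_TO_CATEGORY = {
    "is_model_of": "disease_model",
    "is_marker_of": "disease_biomarker",
    "is_implicated_in": "disease_via_orthology",
    "expressed_in": "expression",
}


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene→term association."""

    gene_id: str
    term_id: str
    category: str
    evidence_code: str
    gene_symbol: str = ""
    qualifiers: Tuple[str, ...] = ()
    negated: bool = False
    reference: str = ""


@dataclass(frozen=True)
class EvidencePolicy:
    """Ordered evidence tiers; earlier tiers are preferred.

    The default membership follows the GO Consortium evidence-code
    groupings.  Tiers listed in ``predicted_tiers`` mark a category
    sentence as a prediction ("Predicted to ...").
    """

    tiers: Tuple[Tuple[str, FrozenSetStr], ...] = (
        ("experimental", frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})),
        ("high_throughput", frozenset({"HTP", "HDA", "HMP", "HGI", "HEP"})),
        ("phylogenetic", frozenset({"IBA", "IBD", "IKR", "IRD"})),
        ("curator_author", frozenset({"IC", "TAS", "NAS"})),
        ("computational", frozenset({"ISS", "ISO", "ISA", "ISM", "IGC", "RCA"})),
        ("electronic", frozenset({"IEA"})),
    )
    predicted_tiers: FrozenSetStr = frozenset(
        {"phylogenetic", "computational", "electronic"}
    )

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for _, codes in self.tiers:
            if seen & codes:
                raise ValueError("evidence tiers must be disjoint")
            seen |= codes

    def tier_index(self, code: str) -> int:
        for i, (_, codes) in enumerate(self.tiers):
            if code in codes:
                return i
        logger.warning("evidence code %r not in any tier; treated as lowest", code)
        return len(self.tiers) - 1

    def tier_name(self, code: str) -> str:
        return self.tiers[self.tier_index(code)][0]

    def is_predicted(self, code: str) -> bool:
        return self.tier_name(code) in self.predicted_tiers


@dataclass
class CategoryConfig:
    """Per-data-category policy for trimming and rendering.

    ``max_terms`` defaults to 3 for every category except expression and
    disease, which allow 5.  ``min_depth`` is the minimum longest-path
    distance from the root for a grouping ancestor to be eligible.
    ``prune_direction`` resolves parent/child pairs in the initial set:
    GO categories keep the most granular term (``keep_child``); expression
    keeps the parent to avoid long lists of tissue parts.
    """

    name: str
    ontology: str = ""
    max_terms: int = 3
    min_depth: int = 3
    trim_algorithm: str = "ic_sanchez"
    prune_direction: str = "keep_child"
    blocklist: Set[str] = field(default_factory=set)
    exclude_from_direct_annotation: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if self.prune_direction not in {"keep_child", "keep_parent", "none"}:
            raise ValueError(f"unknown prune direction {self.prune_direction!r}")


def default_configs() -> Dict[str, CategoryConfig]:
    """Default per-category policy."""
    return {
        "molecular_function": CategoryConfig(
            "molecular_function", ontology="go", prune_direction="keep_child"
        ),
        "biological_process": CategoryConfig(
            "biological_process", ontology="go", prune_direction="keep_child"
        ),
        "cellular_component": CategoryConfig(
            "cellular_component", ontology="go", prune_direction="keep_child"
        ),
        "disease_model": CategoryConfig(
            "disease_model", ontology="do", max_terms=5, prune_direction="keep_child"
        ),
        "disease_biomarker": CategoryConfig(
            "disease_biomarker", ontology="do", max_terms=5, prune_direction="keep_child"
        ),
        "disease_via_orthology": CategoryConfig(
            "disease_via_orthology",
            ontology="do",
            max_terms=5,
            prune_direction="keep_child",
        ),
        "expression": CategoryConfig(
            "expression", ontology="anatomy", max_terms=5, prune_direction="keep_parent"
        ),
    }


# ---------------------------------------------------------------------------
# Readers


def read_gaf(path: str) -> List[GeneAnnotation]:
    """Parse a GAF 2.1/2.2 file into annotations.

    Rows whose qualifier column contains ``NOT`` are kept but flagged
    ``negated`` (they must never contribute to a summary).  Malformed rows
    are skipped with a logged count.
    """
    annotations: List[GeneAnnotation] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                skipped += 1
                logger.warning("skipping malformed GAF row at line %d", lineno)
                continue
            db, db_id, symbol, qualifier, term_id, ref, evidence, _, aspect = cols[:9]
            if aspect not in ASPECT_TO_CATEGORY:
                skipped += 1
                logger.warning("skipping GAF row with aspect %r at line %d", aspect, lineno)
                continue
            quals = tuple(q for q in qualifier.split("|") if q)
            negated = "NOT" in quals
            annotations.append(
                GeneAnnotation(
                    gene_id=f"{db}:{db_id}" if db else db_id,
                    gene_symbol=symbol,
                    term_id=term_id,
                    category=ASPECT_TO_CATEGORY[aspect],
                    evidence_code=evidence,
                    qualifiers=tuple(q for q in quals if q != "NOT"),
                    negated=negated,
                    reference=ref,
                )
            )
    if skipped:
        logger.warning("skipped %d malformed GAF rows in %s", skipped, path)
    return annotations


def read_association_tsv(path: str) -> List[GeneAnnotation]:
    """Parse the generic disease/expression TSV.

    Columns: gene_id, term_id, association_type, evidence_code, and an
    optional gene_symbol.  The association type determines the data
    category (``is_model_of`` → disease relevance, ``is_marker_of`` →
    disease biomarker, ``is_implicated_in`` → disease of a human ortholog,
    ``expressed_in`` → tissue expression).
    """
    annotations: List[GeneAnnotation] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4 or cols[2] not in ASSOCIATION_TO_CATEGORY:
                skipped += 1
                logger.warning("skipping malformed association row at line %d", lineno)
                continue
            gene_id, term_id, assoc, evidence = cols[:4]
            annotations.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    gene_symbol=cols[4] if len(cols) > 4 else "",
                    term_id=term_id,
                    category=ASSOCIATION_TO_CATEGORY[assoc],
                    evidence_code=evidence,
                )
            )
    if skipped:
        logger.warning("skipped %d malformed association rows in %s", skipped, path)
    return annotations


# ---------------------------------------------------------------------------
# Selection


def prioritize_by_evidence(
    annotations: Sequence[GeneAnnotation], policy: EvidencePolicy | None = None
) -> List[GeneAnnotation]:
    """Keep only the annotations in the best non-empty evidence tier.

    The input must all belong to one gene and one category.  Lower tiers
    are discarded entirely: experimental evidence, when present, fully
    determines the sentence for that category.
    """
    policy = policy or EvidencePolicy()
    if not annotations:
        return []
    best = min(policy.tier_index(a.evidence_code) for a in annotations)
    return [a for a in annotations if policy.tier_index(a.evidence_code) == best]


def filter_terms(
    annotations: Sequence[GeneAnnotation],
    config: CategoryConfig,
    graph: OntologyGraph | None = None,
) -> List[GeneAnnotation]:
    """Drop blocklisted and do-not-annotate terms from the direct set.

    Blocklisted terms are banned outright.  Terms on the
    do-not-annotate list are removed as direct annotations but remain
    eligible as grouping ancestors during trimming (the trimmer receives
    only the blocklist, not this list).
    """
    resolve = graph.resolve if graph is not None else (lambda t: t)
    banned = {resolve(t) for t in config.blocklist} | {
        resolve(t) for t in config.exclude_from_direct_annotation
    }
    return [a for a in annotations if resolve(a.term_id) not in banned]


def prune_redundant(
    term_ids: Iterable[str], graph: OntologyGraph, direction: str
) -> Set[str]:
    """Resolve parent/child pairs within a term set.

    ``keep_child`` removes any term that is an ancestor of another term in
    the set (keeps the most granular); ``keep_parent`` removes any term
    that is a descendant of another (keeps the most general); ``none`` is
    the identity.  The result is always an antichain for the first two.
    """
    terms = {graph.resolve(t) for t in term_ids}
    if direction == "none":
        return terms
    if direction not in {"keep_child", "keep_parent"}:
        raise ValueError(f"unknown prune direction {direction!r}")
    drop: Set[str] = set()
    for t in terms:
        others = terms - {t}
        ancestors = graph.ancestors(t)
        if direction == "keep_child" and others & graph.descendants(t):
            drop.add(t)  # t is an ancestor of another term in the set
        elif direction == "keep_parent" and others & ancestors:
            drop.add(t)  # t is a descendant of another term in the set
    return terms - drop
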