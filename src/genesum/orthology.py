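"""Human-ortholog selection and the orthology sentence.

Orthology calls come from a stringent, multi-method prediction set; the
"best" orthologs of a gene are those supported by the most prediction
methods.  At most three are shown; when more than three are equally best,
the sentence switches to "Orthologous to several human genes, including".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from genesum.sentences import join_term_names


@dataclass(frozen=True)
class OrthologRecord:
    """One predicted ortholog of a gene."""

    gene_id: str
    ortholog_symbol: str
    ortholog_name: str
    ortholog_species: str = "Homo sapiens"
    method_count: int = 1
    stringent: bool = True

    def __post_init__(self) -> None:
        if self.stringent and self.method_count < 1:
            raise ValueError("stringent records need method_count >= 1")


def read_ortholog_tsv(path: str) -> List[OrthologRecord]:
    """Read the ortholog table: gene_id, symbol, name, species,
    method_count, stringent_flag."""
    records: List[OrthologRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            gene_id, symbol, name, species, count, stringent = cols[:6]
            records.append(
                OrthologRecord(
                    gene_id=gene_id,
                    ortholog_symbol=symbol,
                    ortholog_name=name,
                    ortholog_species=species,
                    method_count=int(count),
                    stringent=stringent.lower() in {"1", "true", "yes"},
                )
            )
    return records


def select_best_orthologs(
    records: Sequence[OrthologRecord], limit: int = 3
) -> Tuple[List[OrthologRecord], bool]:
    """Keep the orthologs with the maximal prediction-method count.

    ``records`` should already be the stringent human orthologs of a
    single gene.  When more than ``limit`` share the maximum, the first
    ``limit`` under a deterministic ordering (descending method count,
    ascending symbol) are kept and ``truncated`` is set.
    """
    usable = [r for r in records if r.stringent]
    if not usable:
        return [], False
    best_count = max(r.method_count for r in usable)
    best = sorted(
        (r for r in usable if r.method_count == best_count),
        key=lambda r: r.ortholog_symbol,
    )
    truncated = len(best) > limit
    return best[:limit], truncated


def render_orthology_sentence(
    selected: Sequence[OrthologRecord], truncated: bool
) -> str:
    """Render "Orthologous to human SYMBOL (name)" or its truncated
    variant; empty selection yields no sentence (empty string)."""
    if not selected:
        return ""
    names = [f"{r.ortholog_symbol} ({r.ortholog_name})" for r in selected]
    if truncated:
        return "Orthologous to several human genes, including " + join_term_names(names)
    return "Orthologous to human " + join_term_names(names)
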