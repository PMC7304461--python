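"""Template-based sentence rendering.

Each data category has one template: a verb phrase ("Exhibits",
"Involved in", ...), a "several ..., including" variant used when the
term list was trimmed, a "Predicted to ..." variant for non-experimental
evidence, and qualifier phrases ("Contributes to", "Colocalizes with").
Term names are joined with semicolons when more than two are listed,
because ontology term names frequently contain commas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple


class TemplateError(KeyError):
    """Raised when a category has no sentence template."""


@dataclass(frozen=True)
class SentenceTemplate:
    """Phrase table for one data category."""

    category: str
    verb_phrase: str
    several_phrase: str
    predicted_verb_phrase: str = ""
    qualifier_phrases: Mapping[str, str] = field(default_factory=dict)
    multiple_suffix: bool = False  # disease categories mark grouped terms


def default_templates() -> Dict[str, SentenceTemplate]:
    """The standard phrase table for the seven data categories."""
    return {
        "molecular_function": SentenceTemplate(
            category="molecular_function",
            verb_phrase="Exhibits",
            several_phrase="several functions, including",
            predicted_verb_phrase="Predicted to exhibit",
            qualifier_phrases={
                "contributes_to": "Contributes to",
                "colocalizes_with": "Colocalizes with",
            },
        ),
        "biological_process": SentenceTemplate(
            category="biological_process",
            verb_phrase="Involved in",
            several_phrase="several processes, including",
            predicted_verb_phrase="Predicted to be involved in",
        ),
        "cellular_component": SentenceTemplate(
            category="cellular_component",
            verb_phrase="Localizes to",
            several_phrase="several cellular components, including",
            predicted_verb_phrase="Predicted to localize to",
            qualifier_phrases={"colocalizes_with": "Colocalizes with"},
        ),
        "disease_model": SentenceTemplate(
            category="disease_model",
            verb_phrase="Used to study",
            several_phrase="several diseases, including",
            predicted_verb_phrase="Predicted to be used to study",
            multiple_suffix=True,
        ),
        "disease_biomarker": SentenceTemplate(
            category="disease_biomarker",
            verb_phrase="Biomarker for",
            several_phrase="several diseases, including",
            predicted_verb_phrase="Predicted to be a biomarker for",
            multiple_suffix=True,
        ),
        "disease_via_orthology": SentenceTemplate(
            category="disease_via_orthology",
            verb_phrase="Human ortholog(s) of this gene implicated in",
            several_phrase="several diseases, including",
            predicted_verb_phrase="Human ortholog(s) of this gene implicated in",
            multiple_suffix=True,
        ),
        "expression": SentenceTemplate(
            category="expression",
            verb_phrase="Expressed in",
            several_phrase="several structures, including",
            predicted_verb_phrase="Predicted to be expressed in",
        ),
    }


def join_term_names(names: Sequence[str]) -> str:
    """Join term names for a sentence.

    One name stands alone; two are joined with " and "; three or more are
    semicolon-separated with "; and " before the last.
    """
    if not names:
        raise ValueError("cannot join an empty name list")
    if len(names) == 1:
        return names[0]
    if len(names) == 2:
        return f"{names[0]} and {names[1]}"
    return "; ".join(names[:-1]) + f"; and {names[-1]}"


def render_sentence(
    template: SentenceTemplate,
    names: Sequence[str],
    trimmed: bool = False,
    predicted: bool = False,
    qualifier: Optional[str] = None,
    multiple_flags: Optional[Sequence[bool]] = None,
    subject: Optional[str] = None,
) -> str:
    """Render one data-category sentence.

    The qualifier phrase (e.g. "Contributes to") replaces the verb phrase
    when a qualifier is set; otherwise the predicted or plain verb phrase
    is used.  When ``trimmed`` is true the "several ..., including"
    variant fires.  Disease templates append " (multiple)" to any name
    whose flag marks it as standing for more than one annotated term.
    ``subject`` (a gene symbol) turns the sentence into a full clause,
    e.g. "atgp-2 contributes to L-amino acid transmembrane transporter
    activity".
    """
    if not names:
        raise ValueError("cannot render a sentence with no terms")
    if qualifier is not None:
        try:
            verb = template.qualifier_phrases[qualifier]
        except KeyError as exc:
            raise TemplateError(
                f"category {template.category!r} has no phrase for "
                f"qualifier {qualifier!r}"
            ) from exc
    elif predicted:
        verb = template.predicted_verb_phrase or template.verb_phrase
    else:
        verb = template.verb_phrase
    rendered = list(names)
    if template.multiple_suffix and multiple_flags:
        rendered = [
            f"{n} (multiple)" if flag else n
            for n, flag in zip(rendered, multiple_flags)
        ]
    joined = join_term_names(rendered)
    if trimmed:
        sentence = f"{verb} {template.several_phrase} {joined}"
    else:
        sentence = f"{verb} {joined}"
    if subject:
        sentence = f"{subject} {sentence[0].lower()}{sentence[1:]}"
    return sentence


CATEGORY_ORDER: Tuple[str, ...] = (
    "molecular_function",
    "biological_process",
    "cellular_component",
    "disease_model",
    "disease_biomarker",
    "disease_via_orthology",
    "expression",
    "orthology",
)


def assemble_summary(category_sentences: Sequence[str]) -> str:
    """Concatenate category sentences into the final summary text.

    Sentences are joined with ". " and the summary ends with "."; an
    empty list yields an empty summary.
    """
    sentences = [s for s in category_sentences if s]
    if not sentences:
        return ""
    return ". ".join(sentences) + "."
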