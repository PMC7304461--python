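"""Structured configuration loading.

A YAML (or JSON — YAML is a superset) config file customizes per-category
policy and wording without code changes:

.. code-block:: yaml

    categories:
      molecular_function:
        ontology: go
        max_terms: 3
        min_depth: 3
        trim_algorithm: ic_sanchez
        prune_direction: keep_child
        blocklist: [GO:0005515]
        exclude_from_direct_annotation: [GO:0005488]
        template:
          verb_phrase: Exhibits
          several_phrase: several functions, including
          predicted_verb_phrase: Predicted to exhibit
          qualifier_phrases:
            contributes_to: Contributes to

Categories absent from the file keep their defaults.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Mapping, Tuple

import yaml

from genesum.annotations import CategoryConfig, default_configs
from genesum.sentences import SentenceTemplate, default_templates


def load_config(
    path: str,
) -> Tuple[Dict[str, CategoryConfig], Dict[str, SentenceTemplate]]:
    """Read the category/template config file, merged over the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    configs = default_configs()
    templates = default_templates()
    for name, entry in (data.get("categories") or {}).items():
        entry = dict(entry or {})
        tpl_entry = entry.pop("template", None)
        base = configs.get(name, CategoryConfig(name))
        fields = {}
        for key in (
            "ontology",
            "max_terms",
            "min_depth",
            "trim_algorithm",
            "prune_direction",
        ):
            if key in entry:
                fields[key] = entry[key]
        for key in ("blocklist", "exclude_from_direct_annotation"):
            if key in entry:
                fields[key] = set(entry[key] or ())
        configs[name] = replace(base, **fields)
        if tpl_entry:
            tpl_base = templates.get(
                name, SentenceTemplate(category=name, verb_phrase="", several_phrase="")
            )
            tpl_fields = {
                k: tpl_entry[k]
                for k in (
                    "verb_phrase",
                    "several_phrase",
                    "predicted_verb_phrase",
                    "multiple_suffix",
                )
                if k in tpl_entry
            }
            if "qualifier_phrases" in tpl_entry:
                tpl_fields["qualifier_phrases"] = dict(tpl_entry["qualifier_phrases"])
            templates[name] = replace(tpl_base, **tpl_fields)
    return configs, templates
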