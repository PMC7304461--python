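"""Ontology-graph trimming: compress an annotated term set to a few
grouping ancestors.

Two algorithms are provided.  The LCA-based trimmer selects lowest common
ancestors (generalized to arbitrary set sizes as *minimal covering
candidates*: candidates no deeper candidate can replace without losing
coverage) and, when there are too many, solves the resulting maximum
coverage problem greedily.  The IC-weighted trimmer considers *every*
common ancestor at or below the minimum-depth frontier plus the initial
terms themselves, and greedily maximizes covered-count × information
content, trading a little coverage for more specific terms.

Both inherit the classic greedy (1 − 1/e) approximation guarantee for
cardinality-constrained maximum coverage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

from genesum.ontology import OntologyGraph
from genesum.annotations import CategoryConfig


@dataclass
class TrimResult:
    """Outcome of trimming an initial term set.

    ``trimmed`` is true when information was compressed: either some
    initial term is left uncovered, or the selection replaced initial
    terms with grouping ancestors.  ``multiple_flags`` marks selected
    terms that stand for more than one initial term (rendered with a
    "(multiple)" suffix in disease sentences).
    """

    selected: List[str]
    covers: Dict[str, FrozenSet[str]]
    coverage: float
    trimmed: bool
    multiple_flags: Dict[str, bool] = field(default_factory=dict)

    @property
    def covered(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.covers.values():
            out |= s
        return out


def greedy_set_cover(
    candidates: Mapping[str, FrozenSet[str]],
    weights: Mapping[str, float] | None = None,
    max_picks: int = 3,
    depths: Mapping[str, int] | None = None,
) -> List[str]:
    """Greedy maximum coverage over weighted candidates.

    Iteratively picks the candidate maximizing (newly covered count ×
    weight) until ``max_picks`` terms are selected, everything is covered,
    or no candidate adds coverage.  Ties are broken by greater depth
    (more specific term), then lexicographically smaller id, making the
    result deterministic.
    """
    if max_picks < 1:
        raise ValueError("max_picks must be >= 1")
    weights = weights or {}
    depths = depths or {}
    uncovered: Set[str] = set()
    for covered in candidates.values():
        uncovered |= covered
    selected: List[str] = []
    remaining = dict(candidates)
    while uncovered and len(selected) < max_picks:
        best: Optional[str] = None
        best_key: Tuple[float, int, str] | None = None
        for cand, covered in remaining.items():
            gain = len(covered & uncovered)
            if gain == 0:
                continue
            score = gain * weights.get(cand, 1.0)
            # negated id gives "smaller id wins" under max(); ids are
            # compared via a sortable inverse below instead.
            key = (score, depths.get(cand, 0), _inv(cand))
            if best_key is None or key > best_key:
                best, best_key = cand, key
        if best is None:
            break
        selected.append(best)
        uncovered -= remaining.pop(best)
    return selected


def _inv(s: str) -> Tuple[int, ...]:
    """Order-reversing encoding so max() prefers the lexicographically
    smaller id."""
    return tuple(-ord(c) for c in s) + (1,)


def _make_result(
    initial: Set[str],
    selected: List[str],
    candidates: Mapping[str, FrozenSet[str]],
) -> TrimResult:
    covers = {s: candidates[s] for s in selected}
    covered: Set[str] = set()
    for s in selected:
        covered |= covers[s]
    coverage = len(covered & initial) / len(initial)
    trimmed = (covered & initial != initial) or any(s not in initial for s in selected)
    multiple = {s: len(covers[s]) > 1 for s in selected}
    return TrimResult(
        selected=selected,
        covers=covers,
        coverage=coverage,
        trimmed=trimmed,
        multiple_flags=multiple,
    )


def minimal_covering_candidates(
    candidates: Mapping[str, FrozenSet[str]], graph: OntologyGraph
) -> Dict[str, FrozenSet[str]]:
    """Restrict to lowest candidates: drop any candidate that has a
    candidate descendant covering the same subset of initial terms.

    For two terms this is exactly the LCA set; an initial term with no
    shared ancestor survives as the LCA of itself.
    """
    keep: Dict[str, FrozenSet[str]] = {}
    for cand, covered in candidates.items():
        dominated = any(
            d in candidates and candidates[d] == covered
            for d in graph.descendants(cand)
        )
        if not dominated:
            keep[cand] = covered
    return keep


def trim_lca(
    initial: Iterable[str], graph: OntologyGraph, config: CategoryConfig
) -> TrimResult:
    """LCA-based trimming (unweighted maximum coverage).

    Candidates are the minimal covering candidates at depth ≥
    ``config.min_depth`` (initial terms always stand for themselves).  If
    they fit within ``max_terms`` they are all returned; otherwise an
    unweighted greedy set cover selects the best ``max_terms`` of them.
    """
    initial_set = {graph.resolve(t) for t in initial}
    if not initial_set:
        raise ValueError("initial term set must be non-empty")
    candidates = graph.covering_candidates(
        initial_set, config.min_depth, blocklist=config.blocklist
    )
    candidates = minimal_covering_candidates(candidates, graph)
    if len(candidates) <= config.max_terms:
        selected = sorted(candidates, key=lambda t: (-graph.depth(t), t))
        return _make_result(initial_set, selected, candidates)
    depths = {c: graph.depth(c) for c in candidates}
    selected = greedy_set_cover(
        candidates, weights=None, max_picks=config.max_terms, depths=depths
    )
    return _make_result(initial_set, selected, candidates)


def trim_ic(
    initial: Iterable[str],
    graph: OntologyGraph,
    ic_values: Mapping[str, float] | Callable[[str], float],
    config: CategoryConfig,
) -> TrimResult:
    """IC-weighted trimming.

    Every covering candidate (all common ancestors at depth ≥ min_depth,
    not just the LCAs, plus the initial terms) competes in a weighted
    greedy set cover with its information content as weight.  Ancestors
    below the LCA can win when their higher IC outweighs lost coverage;
    with no eligible shared ancestors the highest-IC initial terms are
    kept.
    """
    initial_set = {graph.resolve(t) for t in initial}
    if not initial_set:
        raise ValueError("initial term set must be non-empty")
    candidates = graph.covering_candidates(
        initial_set, config.min_depth, blocklist=config.blocklist
    )
    if callable(ic_values):
        weights = {c: float(ic_values(c)) for c in candidates}
    else:
        weights = {c: float(ic_values[c]) for c in candidates}
    depths = {c: graph.depth(c) for c in candidates}
    selected = greedy_set_cover(
        candidates, weights=weights, max_picks=config.max_terms, depths=depths
    )
    return _make_result(initial_set, selected, candidates)


def trim_naive(
    initial: Iterable[str], graph: OntologyGraph, config: CategoryConfig
) -> TrimResult:
    """Cut-off baseline: keep the first ``max_terms`` initial terms
    (sorted by id) with no ancestor grouping."""
    initial_set = {graph.resolve(t) for t in initial}
    if not initial_set:
        raise ValueError("initial term set must be non-empty")
    selected = sorted(initial_set)[: config.max_terms]
    candidates = {t: frozenset({t}) for t in initial_set}
    return _make_result(initial_set, selected, candidates)


def exact_cover_oracle(
    candidates: Mapping[str, FrozenSet[str]],
    weights: Mapping[str, float] | None = None,
    max_picks: int = 3,
) -> List[str]:
    """Exhaustive maximum-coverage solver for small instances (test oracle).

    Enumerates every candidate subset of size ≤ ``max_picks`` and returns
    the one maximizing covered count, preferring smaller selections, then
    higher total weight; deterministic via id-tuple tie-break.  Refuses
    instances with more than 20 candidates.
    """
    if len(candidates) > 20:
        raise ValueError("oracle limited to <= 20 candidates")
    weights = weights or {}
    ids = sorted(candidates)
    best = None
    best_sel: List[str] = []
    for k in range(0, min(max_picks, len(ids)) + 1):
        for combo in itertools.combinations(ids, k):
            covered: Set[str] = set()
            for c in combo:
                covered |= candidates[c]
            total_w = sum(weights.get(c, 1.0) for c in combo)
            key = (len(covered), -len(combo), total_w, tuple(_inv(c) for c in combo))
            if best is None or key > best:
                best, best_sel = key, list(combo)
    return best_sel
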