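"""Trimming tests: greedy set cover against an exhaustive oracle, LCA
selection on the two-hub anatomy fixture, and IC-weighted behavior."""

import random

import pytest

from genesum.annotations import CategoryConfig
from genesum.fixtures import FixtureSpec, fig3_like_fixture, random_dag
from genesum.information_content import ic_sanchez_table
from genesum.trimming import (
    exact_cover_oracle,
    greedy_set_cover,
    minimal_covering_candidates,
    trim_ic,
    trim_lca,
    trim_naive,
)

from conftest import make_graph

GREEDY_BOUND = 1 - 1 / 2.718281828459045


def F(*xs):
    return frozenset(xs)


class TestGreedySetCover:
    def test_optimal_two_candidate_cover(self):
        cands = {"a1": F("t1", "t2", "t3"), "a2": F("t3", "t4"), "a3": F("t4")}
        assert greedy_set_cover(cands, max_picks=3) == ["a1", "a2"]

    def test_single_covering_candidate(self):
        cands = {"a": F("t1", "t2")}
        assert greedy_set_cover(cands, max_picks=3) == ["a"]

    def test_weight_breaks_equal_coverage(self):
        cands = {"a": F("t1"), "b": F("t2")}
        assert greedy_set_cover(cands, {"a": 1.0, "b": 2.0}, max_picks=1) == ["b"]

    def test_halts_when_nothing_adds_coverage(self):
        cands = {"a": F("t1"), "b": F("t1")}
        assert greedy_set_cover(cands, max_picks=5) == ["a"]

    def test_max_picks_validated(self):
        with pytest.raises(ValueError):
            greedy_set_cover({"a": F("t")}, max_picks=0)

    def test_tie_break_prefers_depth_then_smaller_id(self):
        cands = {"a": F("t1"), "b": F("t2")}
        assert greedy_set_cover(cands, max_picks=1) == ["a"]
        assert greedy_set_cover(cands, max_picks=1, depths={"b": 5}) == ["b"]


class TestExactOracle:
    def test_three_candidate_example(self):
        cands = {"a1": F("t1", "t2", "t3"), "a2": F("t3", "t4"), "a3": F("t4")}
        assert set(exact_cover_oracle(cands, max_picks=3)) == {"a1", "a2"}

    def test_full_cover_when_picks_unbounded(self):
        cands = {c: F(c) for c in "abcde"}
        sel = exact_cover_oracle(cands, max_picks=5)
        assert set(sel) == set("abcde")

    def test_empty_candidates(self):
        assert exact_cover_oracle({}, max_picks=3) == []

    def test_refuses_large_instances(self):
        cands = {f"c{i}": F(f"t{i}") for i in range(21)}
        with pytest.raises(ValueError):
            exact_cover_oracle(cands)


def _random_instance(rng, n_initial=None, n_extra=None):
    n_initial = n_initial or rng.randint(3, 12)
    universe = [f"t{i}" for i in range(n_initial)]
    cands = {t: F(t) for t in universe}
    for j in range(n_extra if n_extra is not None else rng.randint(1, 8)):
        size = rng.randint(1, n_initial)
        cands[f"a{j}"] = frozenset(rng.sample(universe, size))
    if len(cands) > 20:
        cands = dict(list(cands.items())[:20])
    return set(universe), cands


def test_greedy_meets_approximation_bound_vs_oracle():
    rng = random.Random(202)
    for _ in range(200):
        universe, cands = _random_instance(rng)
        max_picks = rng.randint(1, 4)
        greedy = greedy_set_cover(cands, max_picks=max_picks)
        oracle = exact_cover_oracle(cands, max_picks=max_picks)
        g_cov = len(set().union(*(cands[c] for c in greedy)) & universe) if greedy else 0
        o_cov = len(set().union(*(cands[c] for c in oracle)) & universe) if oracle else 0
        assert g_cov >= GREEDY_BOUND * o_cov - 1e-9
        if o_cov == len(universe):  # a full cover exists within max_picks
            assert g_cov >= GREEDY_BOUND * len(universe) - 1e-9


class TestTrimLca:
    def test_two_hub_fixture_selects_exactly_the_hubs(self):
        graph, initial, expected = fig3_like_fixture()
        cfg = CategoryConfig("expr", max_terms=5, min_depth=3)
        result = trim_lca(initial, graph, cfg)
        assert set(result.selected) == expected
        assert result.coverage == 1.0
        assert result.trimmed  # ancestors replaced the initial terms
        assert all(result.multiple_flags[t] for t in result.selected)

    def test_zero_min_depth_admits_the_root(self):
        graph, initial, _ = fig3_like_fixture()
        cfg = CategoryConfig("expr", max_terms=5, min_depth=0)
        result = trim_lca(initial, graph, cfg)
        assert result.selected == ["AO:0000001"]  # the root covers everything

    def test_max_terms_one_takes_larger_hub(self):
        graph, initial, _ = fig3_like_fixture()
        cfg = CategoryConfig("expr", max_terms=1, min_depth=3)
        result = trim_lca(initial, graph, cfg)
        assert result.selected == ["AO:0000006"]  # pharynx covers 3 of 5
        assert result.coverage == pytest.approx(3 / 5)
        assert result.trimmed

    def test_unrelated_deep_terms_pass_through_unchanged(self):
        g = make_graph(
            [
                ("a1", "a0", "is_a"), ("a2", "a1", "is_a"), ("a3", "a2", "is_a"),
                ("b1", "b0", "is_a"), ("b2", "b1", "is_a"), ("b3", "b2", "is_a"),
            ]
        )
        cfg = CategoryConfig("mf", max_terms=3, min_depth=3)
        result = trim_lca({"a3", "b3"}, g, cfg)
        assert set(result.selected) == {"a3", "b3"}
        assert not result.trimmed
        assert result.coverage == 1.0

    def test_empty_initial_rejected(self):
        graph, _, _ = fig3_like_fixture()
        with pytest.raises(ValueError):
            trim_lca(set(), graph, CategoryConfig("x"))

    def test_full_coverage_when_max_terms_unconstrained(self):
        rng = random.Random(33)
        for seed in range(10):
            g = random_dag(FixtureSpec(n_terms=40, seed=800 + seed))
            ids = sorted(g.terms)
            initial = set(rng.sample(ids, 6))
            cfg = CategoryConfig("x", max_terms=50, min_depth=3)
            result = trim_lca(initial, g, cfg)
            assert result.coverage == 1.0

    def test_selected_terms_respect_depth_floor(self):
        rng = random.Random(44)
        for seed in range(20):
            g = random_dag(FixtureSpec(n_terms=50, seed=900 + seed))
            ids = sorted(g.terms)
            initial = set(rng.sample(ids, 8))
            cfg = CategoryConfig("x", max_terms=3, min_depth=3)
            for result in (
                trim_lca(initial, g, cfg),
                trim_ic(initial, g, ic_sanchez_table(g), cfg),
            ):
                for t in result.selected:
                    assert t in initial or g.depth(t) >= 3

    def test_greedy_cap_meets_bound_vs_exhaustive_subsets(self):
        import itertools

        rng = random.Random(55)
        for seed in range(10):
            g = random_dag(FixtureSpec(n_terms=30, seed=950 + seed))
            ids = sorted(g.terms)
            initial = set(rng.sample(ids, 10))
            cfg = CategoryConfig("x", max_terms=3, min_depth=2)
            result = trim_lca(initial, g, cfg)
            cands = minimal_covering_candidates(
                g.covering_candidates(initial, cfg.min_depth), g
            )
            best = 0
            for combo in itertools.combinations(sorted(cands), min(3, len(cands))):
                covered = set().union(*(cands[c] for c in combo))
                best = max(best, len(covered))
            assert len(result.covered) >= GREEDY_BOUND * best - 1e-9


class TestTrimIc:
    def test_deeper_ancestor_with_higher_ic_beats_lca(self):
        # chain to an LCA at depth 3, then a tighter ancestor below it
        g = make_graph(
            [
                ("s1", "root", "is_a"), ("s2", "s1", "is_a"), ("lca", "s2", "is_a"),
                ("mid", "lca", "is_a"),
                ("t1", "mid", "is_a"), ("t2", "mid", "is_a"),
            ]
        )
        weights = {"lca": 1.0, "mid": 2.0, "t1": 2.5, "t2": 2.5}
        cfg = CategoryConfig("x", max_terms=1, min_depth=3)
        result = trim_ic({"t1", "t2"}, g, weights, cfg)
        assert result.selected == ["mid"]
        assert result.coverage == 1.0

    def test_no_shared_ancestors_keeps_highest_ic_initial_terms(self):
        g = make_graph(
            [("a", "root", "is_a"), ("b", "root", "is_a"),
             ("c", "root", "is_a"), ("d", "root", "is_a")]
        )
        weights = {"a": 1.0, "b": 5.0, "c": 3.0, "d": 2.0}
        cfg = CategoryConfig("x", max_terms=2, min_depth=3)
        result = trim_ic({"a", "b", "c", "d"}, g, weights, cfg)
        assert result.selected == ["b", "c"]
        assert result.trimmed  # half the terms were dropped

    def test_identity_when_terms_fit_and_cover_themselves_best(self):
        g = make_graph([("a", "root", "is_a"), ("b", "root", "is_a")])
        weights = {"a": 2.0, "b": 2.0}
        cfg = CategoryConfig("x", max_terms=3, min_depth=3)
        result = trim_ic({"a", "b"}, g, weights, cfg)
        assert set(result.selected) == {"a", "b"}
        assert not result.trimmed

    def test_callable_ic_source(self):
        g = make_graph([("a", "root", "is_a"), ("b", "root", "is_a")])
        cfg = CategoryConfig("x", max_terms=1, min_depth=3)
        result = trim_ic({"a", "b"}, g, lambda t: {"a": 1.0, "b": 9.0}[t], cfg)
        assert result.selected == ["b"]


class TestTrimNaive:
    def test_cutoff_keeps_first_terms(self):
        g = make_graph([("a", "r", "is_a"), ("b", "r", "is_a"), ("c", "r", "is_a")])
        cfg = CategoryConfig("x", max_terms=2)
        result = trim_naive({"a", "b", "c"}, g, cfg)
        assert result.selected == ["a", "b"]
        assert result.trimmed
        assert result.coverage == pytest.approx(2 / 3)


def test_deterministic_selection_across_runs():
    rng = random.Random(66)
    g = random_dag(FixtureSpec(n_terms=60, seed=77))
    ids = sorted(g.terms)
    cfg = CategoryConfig("x", max_terms=3, min_depth=3)
    table = ic_sanchez_table(g)
    for _ in range(10):
        initial = set(rng.sample(ids, 9))
        assert trim_lca(initial, g, cfg).selected == trim_lca(initial, g, cfg).selected
        assert (
            trim_ic(initial, g, table, cfg).selected
            == trim_ic(initial, g, table, cfg).selected
        )
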