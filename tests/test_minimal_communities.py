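"""Exact minimal-community selection, classification, and summaries."""

from __future__ import annotations

import numpy as np
import pytest

from metapot import (
    MetabolicNetwork,
    Reaction,
    SeedCondition,
    SystemSpec,
    abundance_summary,
    enumerate_solutions,
    filter_targets,
    solve_minimum,
    substitutable_groups,
)

from conftest import exhaustive_mincom, random_community, random_seeds

COND_A = SeedCondition("seed_a", frozenset({"A"}))


class TestFilterTargets:
    def test_partition(self, fixture_suite):
        fx = fixture_suite["interchangeable_producers"]
        tset = filter_targets(fx["system"], fx["condition"], {"t1", "t4", "ghost"})
        assert tset.producible == {"t1", "t4"}
        assert tset.unproducible == {"ghost"}

    def test_seed_id_unproducible_unless_regenerated(self, fixture_suite):
        fx = fixture_suite["interchangeable_producers"]
        tset = filter_targets(fx["system"], fx["condition"], {"A", "t1"})
        assert "A" in tset.unproducible  # exclusive seed convention

    def test_empty_request_rejected(self, fixture_suite):
        fx = fixture_suite["interchangeable_producers"]
        with pytest.raises(ValueError, match="empty target set"):
            filter_targets(fx["system"], fx["condition"], set())

    def test_metagenome_scale_rejected(self, fixture_suite):
        net = fixture_suite["linear_chain"]["network"]
        system = SystemSpec("s", "metagenome", (net,))
        with pytest.raises(ValueError, match="genome_resolved"):
            filter_targets(system, COND_A, {"C"})


class TestSolveMinimum:
    def test_single_producer_k1(self, fixture_suite):
        fx = fixture_suite["interchangeable_producers"]
        k, witness = solve_minimum(fx["system"], fx["condition"], {"t1"})
        assert k == 1
        assert witness == frozenset({"e1"})

    def test_forced_handoff_k2(self, fixture_suite):
        fx = fixture_suite["handoff_pair"]
        k, witness = solve_minimum(fx["system"], fx["condition"], {"C"})
        assert k == 2
        assert witness == frozenset({"m1", "m2"})

    def test_fixture_instances_match_expectations(self, fixture_suite):
        for name in ("interchangeable_producers", "enumeration_12"):
            fx = fixture_suite[name]
            k, _ = solve_minimum(fx["system"], fx["condition"], fx["targets"])
            assert k == fx["expected_k"]


class TestEnumerate:
    @pytest.mark.parametrize("name", ["interchangeable_producers", "enumeration_12"])
    def test_fixture_expectations_and_oracle(self, fixture_suite, name):
        fx = fixture_suite[name]
        sols = enumerate_solutions(fx["system"], fx["condition"], fx["targets"])
        assert sols.k == fx["expected_k"]
        assert sols.n_solutions == fx["expected_n_solutions"]
        assert sols.essential == fx["expected_essential"]
        assert sols.alternative == fx["expected_alternative"]
        classes = substitutable_groups(sols).classes
        assert sorted(map(sorted, classes)) == sorted(
            map(sorted, fx["expected_classes"])
        )
        # re-verify the stored expectations against brute force
        k_oracle, sols_oracle = exhaustive_mincom(
            fx["system"], fx["condition"], fx["targets"]
        )
        assert k_oracle == sols.k
        assert set(sols_oracle) == set(sols.solutions)

    def test_unique_solution_means_all_essential(self, fixture_suite):
        fx = fixture_suite["handoff_pair"]
        sols = enumerate_solutions(fx["system"], fx["condition"], {"C"})
        assert sols.n_solutions == 1
        assert sols.essential == sols.key_species == frozenset({"m1", "m2"})
        assert sols.alternative == frozenset()
        assert sols.mc_ks_percent == 100.0
        assert substitutable_groups(sols).classes == []

    def test_mc_ks_100_iff_unique(self, fixture_suite):
        fx = fixture_suite["enumeration_12"]
        sols = enumerate_solutions(fx["system"], fx["condition"], fx["targets"])
        assert sols.n_solutions > 1
        assert sols.mc_ks_percent < 100.0

    def test_minimality_of_every_solution(self, fixture_suite):
        from metapot import community_scope

        fx = fixture_suite["enumeration_12"]
        sols = enumerate_solutions(fx["system"], fx["condition"], fx["targets"])
        nets = {m.id: m for m in fx["system"].members}
        for sol in sols.solutions:
            for member in sol:
                rest = tuple(nets[m] for m in sorted(sol - {member}))
                reduced = SystemSpec("s", "genome_resolved", rest)
                assert not fx["targets"] <= community_scope(reduced, fx["condition"])

    def test_essential_removal_breaks_full_community(self, fixture_suite):
        from metapot import community_scope

        fx = fixture_suite["enumeration_12"]
        sols = enumerate_solutions(fx["system"], fx["condition"], fx["targets"])
        nets = {m.id: m for m in fx["system"].members}
        for member in sols.essential:
            rest = tuple(n for mid, n in sorted(nets.items()) if mid != member)
            reduced = SystemSpec("s", "genome_resolved", rest)
            assert not fx["targets"] <= community_scope(reduced, fx["condition"])

    def test_cap_suppresses_classification(self):
        # 8 interchangeable producers of one target, k=1 -> 8 solutions
        members = tuple(
            MetabolicNetwork(f"p{i}", (Reaction(f"r{i}", frozenset({"A"}), frozenset({"t"})),))
            for i in range(8)
        )
        system = SystemSpec("s", "genome_resolved", members)
        sols = enumerate_solutions(system, COND_A, {"t"}, cap=3)
        assert sols.capped
        assert sols.key_species == frozenset()
        with pytest.raises(ValueError, match="suppressed"):
            substitutable_groups(sols)


def test_random_instances_match_exhaustive_oracle():
    rng = np.random.default_rng(909)
    checked = 0
    for _ in range(12):
        system = random_community(rng, n_members=int(rng.integers(5, 9)))
        pooled_scope = None
        from metapot import community_scope, union_network

        seeds = random_seeds(rng, union_network(system), n=3)
        cond = SeedCondition("rand", seeds)
        pooled_scope = community_scope(system, cond)
        if len(pooled_scope) < 2:
            continue
        targets = frozenset(
            rng.choice(sorted(pooled_scope), size=min(3, len(pooled_scope)), replace=False)
        )
        k_oracle, sols_oracle = exhaustive_mincom(system, cond, targets)
        sols = enumerate_solutions(system, cond, targets)
        assert sols.k == k_oracle
        assert set(sols.solutions) == set(sols_oracle)
        checked += 1
    assert checked >= 5  # enough non-degenerate instances exercised


def test_substitutability_consistent_with_swap_oracle():
    # independent oracle: recompute the pairwise swap relation by brute force
    # and its connected components with networkx
    import networkx as nx
    from itertools import combinations

    rng = np.random.default_rng(910)
    checked = 0
    for _ in range(8):
        system = random_community(rng, n_members=6)
        from metapot import community_scope, union_network

        seeds = random_seeds(rng, union_network(system), n=3)
        cond = SeedCondition("rand", seeds)
        scope = community_scope(system, cond)
        if len(scope) < 2:
            continue
        targets = frozenset(rng.choice(sorted(scope), size=2, replace=False))
        sols = enumerate_solutions(system, cond, targets)
        classes = substitutable_groups(sols).classes
        solution_set = set(sols.solutions)
        graph = nx.Graph()
        graph.add_nodes_from(sols.alternative)
        for a, b in combinations(sorted(sols.alternative), 2):
            fwd = all((s - {a}) | {b} in solution_set for s in solution_set if a in s)
            back = all((s - {b}) | {a} in solution_set for s in solution_set if b in s)
            if fwd and back:
                graph.add_edge(a, b)
        oracle = sorted(sorted(c) for c in nx.connected_components(graph))
        assert sorted(sorted(c) for c in classes) == oracle
        checked += 1
    assert checked >= 3


class TestAbundanceSummary:
    def _solutions(self, fixture_suite):
        fx = fixture_suite["interchangeable_producers"]
        return enumerate_solutions(fx["system"], fx["condition"], fx["targets"])

    def test_cumulative_addition(self, fixture_suite):
        sols = self._solutions(fixture_suite)
        abundances = {"e1": 1.5, "e2": 2.0, "e3": 0.0, "p1": 0.25, "p2": 0.25}
        summary = abundance_summary(sols, abundances)
        assert summary["key_species_abundance_percent"] == pytest.approx(4.0)
        assert summary["essential_abundance_percent"] == pytest.approx(3.5)

    def test_all_zero(self, fixture_suite):
        sols = self._solutions(fixture_suite)
        summary = abundance_summary(sols, dict.fromkeys(sols.key_species, 0.0))
        assert summary["key_species_abundance_percent"] == 0.0

    def test_missing_member_listed(self, fixture_suite):
        sols = self._solutions(fixture_suite)
        with pytest.raises(ValueError, match="e1"):
            abundance_summary(sols, {"e2": 1.0})


def test_world_planted_structure_recovered(small_world):
    basal = small_world.conditions["basal_medium"]
    for system in small_world.systems():
        if system.scale != "genome_resolved":
            continue
        truth = small_world.manifest["mincom"][system.site]
        tset = filter_targets(system, basal, truth["targets"])
        assert tset.producible == frozenset(truth["targets"])
        sols = enumerate_solutions(system, basal, tset.producible)
        assert sols.k == truth["k"]
        assert sols.n_solutions == truth["n_solutions"]
        assert sorted(sols.essential) == truth["essential"]
        classes = substitutable_groups(sols).classes
        assert sorted(map(sorted, classes)) == sorted(map(sorted, truth["classes"]))
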