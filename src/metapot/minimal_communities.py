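"""Minimal communities: smallest member subsets producing target metabolites.

Given a genome-resolved system, a seed condition, and target metabolites, find
the minimum number k of members whose mixed-bag scope covers every target, and
enumerate *all* size-k solutions. Members are then classified: *key species*
(in at least one solution), split into *essential* syntrophic organisms (in
every solution — producibility bottlenecks) and *alternative* syntrophic
organisms (in some but not all — functional redundancy). The MC:KS ratio,
100·k / |key species|, is 100% exactly when a single rigid consortium exists.

The solver is a self-contained exact search: members firing no reaction even
with the full community's products available are pruned (they cannot help any
subset), then subset sizes 1, 2, ... are searched exhaustively in
lexicographic member order, so results are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import chain, combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .community_scope import SystemSpec, community_scope
from .conditions import SeedCondition
from .network_model import DirectedReactionSet, directed_view, expansion_scope

logger = logging.getLogger("metapot")

__all__ = [
    "TargetSet",
    "MinimalCommunitySolutionSet",
    "SubstitutableGroups",
    "filter_targets",
    "solve_minimum",
    "enumerate_solutions",
    "substitutable_groups",
    "abundance_summary",
]

DEFAULT_SOLUTION_CAP = 10_000


@dataclass
class TargetSet:
    """Requested targets split into community-producible and unproducible."""

    site: str
    condition: SeedCondition
    requested: frozenset[str]
    producible: frozenset[str]
    unproducible: frozenset[str]


def filter_targets(
    system: SystemSpec, condition: SeedCondition, requested: Iterable[str]
) -> TargetSet:
    """Partition requested targets by full-community producibility.

    Targets the whole community cannot reach are excluded from solving (no
    subset could reach them either) and reported. Under the seed-exclusive
    scope convention a seed id is unproducible unless some reaction
    regenerates it.
    """
    if system.scale != "genome_resolved":
        raise ValueError("minimal-community selection requires a genome_resolved system")
    requested = frozenset(requested)
    if not requested:
        raise ValueError("empty target set")
    full = community_scope(system, condition)
    producible = requested & full
    return TargetSet(
        site=system.site,
        condition=condition,
        requested=requested,
        producible=producible,
        unproducible=requested - producible,
    )


class _SubsetScoper:
    """Cached per-member rules + pruning for repeated subset scope queries."""

    def __init__(self, system: SystemSpec, condition: SeedCondition):
        self.seeds = condition.seeds
        self.rules_of = {m.id: directed_view(m).rules for m in system.members}
        full_available = (
            expansion_scope(
                DirectedReactionSet(
                    tuple(chain.from_iterable(self.rules_of.values()))
                ),
                self.seeds,
            )
            | self.seeds
        )
        # A member none of whose rules can fire even with everything the full
        # community makes available contributes nothing to any subset's scope.
        self.candidates = sorted(
            mid
            for mid, rules in self.rules_of.items()
            if any(inp <= full_available for inp, _ in rules)
        )

    def scope(self, member_ids: Sequence[str]) -> frozenset[str]:
        rules = tuple(chain.from_iterable(self.rules_of[m] for m in member_ids))
        return expansion_scope(DirectedReactionSet(rules), self.seeds)

    def covers(self, member_ids: Sequence[str], targets: frozenset[str]) -> bool:
        return targets <= self.scope(member_ids)

    def forced_members(self, targets: frozenset[str]) -> list[str]:
        """Members whose removal from the full community breaks coverage.

        Such a member belongs to *every* covering subset (a subset without it
        is contained in candidates-minus-it, whose scope already fails), so
        the search only needs to explore combinations of the rest.
        """
        forced = []
        for m in self.candidates:
            rest = [c for c in self.candidates if c != m]
            if not self.covers(rest, targets):
                forced.append(m)
        return forced


def solve_minimum(
    system: SystemSpec, condition: SeedCondition, targets: Iterable[str]
) -> tuple[int, frozenset[str]]:
    """Exact minimum community size and one witness subset.

    Iterative deepening over subset sizes, restricted to contributing members
    and anchored on the forced members above; ties are broken by
    lexicographic member order. Targets must all be producible by the full
    community (run :func:`filter_targets` first).
    """
    targets = frozenset(targets)
    if not targets:
        raise ValueError("empty target set")
    scoper = _SubsetScoper(system, condition)
    if not scoper.covers(scoper.candidates, targets):
        raise RuntimeError(
            "targets not producible by the full community; filter_targets first"
        )
    forced = scoper.forced_members(targets)
    free = [c for c in scoper.candidates if c not in set(forced)]
    for j in range(0, len(free) + 1):
        for combo in combinations(free, j):
            subset = tuple(sorted(forced + list(combo)))
            if scoper.covers(subset, targets):
                return len(subset), frozenset(subset)
    raise RuntimeError("unreachable: full community covers targets")  # pragma: no cover


@dataclass
class MinimalCommunitySolutionSet:
    """All minimum-size communities for one site plus member classification."""

    site: str
    k: int
    targets: frozenset[str]
    solutions: list[frozenset[str]]
    key_species: frozenset[str]
    essential: frozenset[str]
    alternative: frozenset[str]
    mc_ks_percent: float
    capped: bool = False

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    def to_json(self) -> str:
        return json.dumps(
            {
                "site": self.site,
                "minimal_community_size": self.k,
                "targets": sorted(self.targets),
                "n_solutions": self.n_solutions,
                "solutions": [sorted(s) for s in self.solutions],
                "key_species": sorted(self.key_species),
                "essential": sorted(self.essential),
                "alternative": sorted(self.alternative),
                "mc_ks_percent": self.mc_ks_percent,
                "capped": self.capped,
            },
            indent=2,
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def enumerate_solutions(
    system: SystemSpec,
    condition: SeedCondition,
    targets: Iterable[str],
    k: int | None = None,
    *,
    cap: int = DEFAULT_SOLUTION_CAP,
) -> MinimalCommunitySolutionSet:
    """Enumerate every size-k member subset covering the targets.

    ``k`` defaults to the exact minimum from :func:`solve_minimum`.
    Enumeration follows lexicographic member order. If more than ``cap``
    solutions exist the result is flagged ``capped`` and the classification
    fields are suppressed (an incomplete solution list would misclassify).
    """
    targets = frozenset(targets)
    if k is None:
        k, _ = solve_minimum(system, condition, targets)
    scoper = _SubsetScoper(system, condition)
    forced = scoper.forced_members(targets)
    free = [c for c in scoper.candidates if c not in set(forced)]
    if len(forced) > k:
        raise ValueError(f"k={k} below the number of forced members ({len(forced)})")
    solutions: list[frozenset[str]] = []
    capped = False
    for combo in combinations(free, k - len(forced)):
        subset = frozenset(forced) | frozenset(combo)
        if scoper.covers(tuple(subset), targets):
            solutions.append(subset)
            if len(solutions) > cap:
                capped = True
                break
    if capped:
        logger.warning(
            "site %s: more than %d minimal communities; classification suppressed",
            system.site,
            cap,
        )
        return MinimalCommunitySolutionSet(
            site=system.site,
            k=k,
            targets=targets,
            solutions=solutions[:cap],
            key_species=frozenset(),
            essential=frozenset(),
            alternative=frozenset(),
            mc_ks_percent=float("nan"),
            capped=True,
        )
    key_species = frozenset().union(*solutions)
    essential = frozenset.intersection(*solutions)
    return MinimalCommunitySolutionSet(
        site=system.site,
        k=k,
        targets=targets,
        solutions=solutions,
        key_species=key_species,
        essential=essential,
        alternative=key_species - essential,
        mc_ks_percent=100.0 * k / len(key_species),
    )


@dataclass
class SubstitutableGroups:
    """Interchangeability classes among alternative members.

    Two alternatives belong to one class when swapping either for the other
    maps every solution containing it to another valid solution, the rest of
    the community fixed (the "OR" circles of a power-graph summary; essential
    members are the "AND" part and are excluded). Classes are the connected
    components of the pairwise swap relation.
    """

    classes: list[frozenset[str]]

    def class_of(self, member: str) -> frozenset[str] | None:
        for cls in self.classes:
            if member in cls:
                return cls
        return None

    def to_json(self) -> str:
        return json.dumps({"classes": [sorted(c) for c in self.classes]}, indent=2)


def _swappable(a: str, b: str, solution_set: set[frozenset[str]]) -> bool:
    for sol in solution_set:
        if a in sol and (sol - {a}) | {b} not in solution_set:
            return False
        if b in sol and (sol - {b}) | {a} not in solution_set:
            return False
    return True


def substitutable_groups(result: MinimalCommunitySolutionSet) -> SubstitutableGroups:
    """Partition alternative members by the pairwise swap test."""
    if result.capped:
        raise ValueError("classification suppressed (solution cap exceeded)")
    alts = sorted(result.alternative)
    solution_set = set(result.solutions)
    parent = {a: a for a in alts}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(alts, 2):
        if find(a) != find(b) and _swappable(a, b, solution_set):
            parent[find(b)] = find(a)
    classes: dict[str, set[str]] = {}
    for a in alts:
        classes.setdefault(find(a), set()).add(a)
    return SubstitutableGroups([frozenset(c) for c in sorted(classes.values(), key=min)])


def abundance_summary(
    result: MinimalCommunitySolutionSet, abundances: Mapping[str, float]
) -> dict:
    """Cumulative relative abundance (%) of key species and essential members."""
    missing = sorted(result.key_species - set(abundances))
    if missing:
        raise ValueError(f"missing abundance for key species: {missing}")
    table = pd.DataFrame(
        {
            "member": sorted(result.key_species),
            "abundance_percent": [abundances[m] for m in sorted(result.key_species)],
            "role": [
                "essential" if m in result.essential else "alternative"
                for m in sorted(result.key_species)
            ],
        }
    )
    return {
        "site": result.site,
        "key_species_abundance_percent": float(table["abundance_percent"].sum()),
        "essential_abundance_percent": float(
            table.loc[table["role"] == "essential", "abundance_percent"].sum()
        ),
        "per_member": table,
    }
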