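"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own algorithms: scope is
re-derived by naive repeated rescanning of all rules, minimal communities by
exhaustive subset search, and group counts by hashing row tuples.
"""

from __future__ import annotations

import hashlib
from itertools import combinations
from pathlib import Path

import numpy as np
import pytest

from metapot import (
    MetabolicNetwork,
    Reaction,
    SeedCondition,
    SystemSpec,
    directed_view,
    make_fixture_suite,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def naive_scope(network, seeds, include_seeds=False):
    """Fixpoint by re-scanning every directed rule until nothing changes."""
    rules = list(directed_view(network))
    available = set(seeds)
    produced = set()
    changed = True
    while changed:
        changed = False
        for inputs, outputs in rules:
            if inputs <= available and not outputs <= produced:
                produced |= outputs
                available |= outputs
                changed = True
    return frozenset(produced | set(seeds)) if include_seeds else frozenset(produced)


def exhaustive_mincom(system: SystemSpec, condition: SeedCondition, targets):
    """Brute-force minimum size and all minimum-size covers over 2^n subsets."""
    targets = frozenset(targets)
    members = sorted(m.id for m in system.members)
    nets = {m.id: m for m in system.members}

    def covers(subset):
        pooled = []
        for mid in subset:
            pooled.extend(nets[mid].reactions)
        # ids may repeat across members; MetabolicNetwork tolerates that
        net = MetabolicNetwork("u", tuple(pooled))
        return targets <= naive_scope(net, condition.seeds)

    for k in range(1, len(members) + 1):
        sols = [frozenset(c) for c in combinations(members, k) if covers(c)]
        if sols:
            return k, sols
    raise AssertionError("targets not coverable by full community")


def unique_row_count(matrix_values) -> int:
    """Independent group count: hash each row tuple."""
    return len({hashlib.sha1(repr(tuple(row)).encode()).hexdigest() for row in matrix_values})


# ---------------------------------------------------------------------------
# Random instance generators (test-local, independent of synthetic_data)
# ---------------------------------------------------------------------------


def random_network(rng: np.random.Generator, n_metabolites=30, n_reactions=40,
                   rev_prob=0.3, net_id="rand") -> MetabolicNetwork:
    mets = [f"x{i}" for i in range(n_metabolites)]
    reactions = []
    for i in range(n_reactions):
        reactants = frozenset(rng.choice(mets, size=int(rng.integers(1, 4)), replace=False))
        products = frozenset(rng.choice(mets, size=int(rng.integers(1, 3)), replace=False))
        if not reactants or not products:
            continue
        reactions.append(
            Reaction(f"r{i}", reactants, products, bool(rng.random() < rev_prob))
        )
    return MetabolicNetwork(net_id, tuple(reactions))


def random_seeds(rng: np.random.Generator, network: MetabolicNetwork, n=5) -> frozenset:
    mets = sorted(network.metabolites)
    n = min(n, len(mets))
    return frozenset(rng.choice(mets, size=n, replace=False))


def random_community(rng: np.random.Generator, n_members=6, site="toy") -> SystemSpec:
    members = tuple(
        random_network(
            rng,
            n_metabolites=int(rng.integers(8, 15)),
            n_reactions=int(rng.integers(4, 10)),
            net_id=f"m{j:02d}",
        )
        for j in range(n_members)
    )
    return SystemSpec(site, "genome_resolved", members)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def fixture_suite():
    return make_fixture_suite()


@pytest.fixture(scope="session")
def small_world():
    """One default synthetic world shared by read-only tests."""
    from metapot import WorldConfig, build_world

    return build_world(WorldConfig(seed=7))


@pytest.fixture(scope="session")
def small_world_matrix(small_world):
    from metapot import run_grid

    return run_grid(small_world.systems(), list(small_world.conditions))


def tree_hash(directory: str | Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(directory).rglob("*")):
        if p.is_file():
            h.update(p.relative_to(directory).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()
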