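"""Scopes of multi-member systems: individual, community, and cooperation.

A *system* is one site's metabolic model at one of two scales: a single
community-wide network built from the whole metagenome (``metagenome`` scale),
or the collection of genome-resolved networks of the site's MAGs
(``genome_resolved`` scale). Community producibility uses mixed-bag semantics:
all members' reactions are pooled into one network, the upper bound of
cross-feeding-enabled metabolism with no transporter gating. The *cooperation
potential* (added value) is what the pooled community can synthesize that no
member can alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

from .conditions import SeedCondition
from .network_model import MetabolicNetwork, Reaction, expansion_scope

__all__ = [
    "Scale",
    "SystemSpec",
    "ScopeResult",
    "union_network",
    "individual_scopes",
    "community_scope",
    "cooperation_potential",
]

Scale = Literal["metagenome", "genome_resolved"]


@dataclass
class SystemSpec:
    """One site's model at one scale; metagenome systems have one member."""

    site: str
    scale: Scale
    members: tuple[MetabolicNetwork, ...]

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if not self.members:
            raise ValueError(f"system {self.site}/{self.scale}: at least one member required")
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"system {self.site}/{self.scale}: duplicate member ids")
        if self.scale == "metagenome" and len(self.members) != 1:
            raise ValueError(
                f"system {self.site}/metagenome: expected exactly one member network"
            )

    @property
    def id(self) -> str:
        return f"{self.site}|{self.scale}"

    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


def union_network(system: SystemSpec) -> MetabolicNetwork:
    """Pool all members' reactions into one mixed-bag network.

    The union is by reaction content; duplicate rules carried by several
    members collapse, but reaction provenance stays recoverable from the
    members themselves (used for minimal-community attribution).
    """
    seen: dict[tuple, Reaction] = {}
    for member in system.members:
        for r in member.reactions:
            key = (r.reactants, r.products, r.reversible)
            if key not in seen:
                seen[key] = r
    return MetabolicNetwork(f"{system.id}|union", tuple(seen.values()))


def individual_scopes(
    system: SystemSpec, condition: SeedCondition, *, include_seeds: bool = False
) -> dict[str, frozenset[str]]:
    """Each member's scope computed independently of the others."""
    return {
        m.id: expansion_scope(m, condition.seeds, include_seeds=include_seeds)
        for m in system.members
    }


def community_scope(
    system: SystemSpec, condition: SeedCondition, *, include_seeds: bool = False
) -> frozenset[str]:
    """Scope of the pooled union network; a superset of every member scope."""
    if len(system.members) == 1:
        net = system.members[0]
    else:
        net = union_network(system)
    return expansion_scope(net, condition.seeds, include_seeds=include_seeds)


@dataclass
class ScopeResult:
    """Community and per-member scopes plus the cooperation-only set."""

    system: SystemSpec
    condition: SeedCondition
    community: frozenset[str]
    per_member: Mapping[str, frozenset[str]]
    cooperation_only: frozenset[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "site": self.system.site,
                "scale": self.system.scale,
                "condition": self.condition.name,
                "community_scope": sorted(self.community),
                "per_member_scopes": {
                    mid: sorted(s) for mid, s in sorted(self.per_member.items())
                },
                "cooperation_only": sorted(self.cooperation_only),
            },
            indent=2,
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def cooperation_potential(
    system: SystemSpec, condition: SeedCondition, *, include_seeds: bool = False
) -> ScopeResult:
    """Metabolites producible only by the community, not by any member alone.

    Only meaningful at genome_resolved scale — a metagenome system has a
    single pooled member, so its added value is zero by construction and the
    call is rejected.
    """
    if system.scale != "genome_resolved":
        raise ValueError(
            "cooperation_potential requires a genome_resolved system; "
            f"got scale={system.scale!r} for site {system.site!r}"
        )
    per_member = individual_scopes(system, condition, include_seeds=include_seeds)
    community = community_scope(system, condition, include_seeds=include_seeds)
    union_members: set[str] = set()
    for s in per_member.values():
        union_members |= s
    return ScopeResult(
        system=system,
        condition=condition,
        community=community,
        per_member=per_member,
        cooperation_only=frozenset(community - union_members),
    )
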