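"""Seed conditions: nutrient sets that initialize network expansion.

Five canonical conditions model contrasting nutrient scenarios for oligotrophic
soils: a *basal medium* of inorganic carbon/nitrogen/sulfur sources, water,
oxygen, metal ions and core cofactors (43 compounds), contained in each of the
four richer conditions; *simple sugars* (+7) and *complex sugars* (+21) probing
organic carbon; and *all amino acids* (+20) versus *non-sulfured amino acids*
(+18, lacking only cysteine and methionine) probing organic nitrogen and
sulfur. User-defined conditions extend any parent by union with additions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .network_model import write_seed_file

__all__ = [
    "SeedCondition",
    "ConditionLibrary",
    "ConditionValidationError",
    "CANONICAL_SIZES",
    "build_condition",
    "load_condition_library",
    "canonical_library",
]

CANONICAL_SIZES: Mapping[str, int] = {
    "basal_medium": 43,
    "simple_sugars": 50,
    "complex_sugars": 64,
    "non_sulfured_amino_acids": 61,
    "all_amino_acids": 63,
}

SULFUR_AMINO_ACIDS = frozenset({"CYS", "MET"})


class ConditionValidationError(ValueError):
    """A condition library violates a structural invariant."""


@dataclass(frozen=True)
class SeedCondition:
    """A named seed set, optionally recorded as extending a parent condition."""

    name: str
    seeds: frozenset[str]
    parent: str | None = None
    placeholders: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("condition name must be nonempty")
        object.__setattr__(self, "seeds", frozenset(self.seeds))
        object.__setattr__(self, "placeholders", frozenset(self.placeholders))

    def __len__(self) -> int:
        return len(self.seeds)


def build_condition(
    name: str,
    parent: SeedCondition | None,
    additions: Iterable[str],
    placeholders: Iterable[str] = (),
) -> SeedCondition:
    """Union a parent condition's seeds with additions (overlap allowed)."""
    if not name:
        raise ValueError("condition name must be nonempty")
    additions = frozenset(additions)
    if parent is None:
        return SeedCondition(name, additions, None, frozenset(placeholders))
    return SeedCondition(
        name,
        parent.seeds | additions,
        parent.name,
        parent.placeholders | frozenset(placeholders),
    )


@dataclass
class ConditionLibrary:
    """A validated mapping of condition names to seed conditions."""

    conditions: dict[str, SeedCondition]
    provenance: str = ""

    def __getitem__(self, name: str) -> SeedCondition:
        return self.conditions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.conditions

    def __iter__(self):
        return iter(self.conditions.values())

    def __len__(self) -> int:
        return len(self.conditions)

    def names(self) -> list[str]:
        return list(self.conditions)

    def validate(self) -> None:
        """Check the canonical invariants; raise listing every discrepancy."""
        problems: list[str] = []
        conds = self.conditions
        basal = conds.get("basal_medium")
        for name, expected in CANONICAL_SIZES.items():
            if name in conds and len(conds[name]) != expected:
                problems.append(
                    f"{name}: expected {expected} seeds, found {len(conds[name])}"
                )
        if basal is not None:
            for name, cond in conds.items():
                if name in CANONICAL_SIZES and name != "basal_medium":
                    if not basal.seeds <= cond.seeds:
                        missing = sorted(basal.seeds - cond.seeds)
                        problems.append(
                            f"{name}: basal medium not contained (missing {missing[:5]}...)"
                        )
        if "all_amino_acids" in conds and "non_sulfured_amino_acids" in conds:
            aa = conds["all_amino_acids"].seeds
            ns = conds["non_sulfured_amino_acids"].seeds
            diff = aa - ns
            if not ns <= aa or diff != SULFUR_AMINO_ACIDS:
                problems.append(
                    "all_amino_acids \\ non_sulfured_amino_acids must be exactly "
                    f"{sorted(SULFUR_AMINO_ACIDS)}, found {sorted(diff)}"
                )
        if problems:
            raise ConditionValidationError(
                "condition library failed validation:\n  " + "\n  ".join(problems)
            )

    def export_seed_files(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for cond in self:
            write_seed_file(cond.seeds, directory / f"{cond.name}.txt")


def _library_from_spec(spec: Mapping, provenance: str) -> ConditionLibrary:
    entries = spec.get("conditions")
    if not entries:
        raise ConditionValidationError(f"{provenance}: no conditions defined")
    conditions: dict[str, SeedCondition] = {}
    for entry in entries:
        name = entry.get("name")
        if not name:
            raise ConditionValidationError(f"{provenance}: condition without a name")
        if name in conditions:
            raise ConditionValidationError(f"{provenance}: duplicated condition {name!r}")
        parent_name = entry.get("parent")
        parent = None
        if parent_name is not None:
            if parent_name not in conditions:
                raise ConditionValidationError(
                    f"{provenance}: condition {name!r} extends unknown parent {parent_name!r}"
                )
            parent = conditions[parent_name]
        conditions[name] = build_condition(
            name,
            parent,
            entry.get("members", ()),
            entry.get("placeholders", ()),
        )
    lib = ConditionLibrary(conditions, provenance)
    lib.validate()
    return lib


def load_condition_library(path: str | Path) -> ConditionLibrary:
    """Load and validate a condition library from a YAML file.

    Each entry gives ``name`` plus either explicit ``members`` or a ``parent``
    (defined earlier in the file) and additional members; seeds are the union.
    Placeholder ids standing in for compounds whose published identity is
    unavailable are declared under ``placeholders``.
    """
    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return _library_from_spec(spec, str(path))


def canonical_library() -> ConditionLibrary:
    """The packaged five-condition library (sizes 43/50/64/61/63)."""
    ref = importlib.resources.files("metapot.data").joinpath("conditions.yaml")
    spec = yaml.safe_load(ref.read_text())
    return _library_from_spec(spec, "metapot.data/conditions.yaml")
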