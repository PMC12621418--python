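"""Stoichiometry-free metabolic networks and the network-expansion (scope) engine.

A metabolic network is treated as a Boolean reaction graph: each reaction is a
pair of metabolite sets (reactants, products) plus a reversibility flag, and
producibility is pure reachability — a reaction fires as soon as *all* its
inputs are available, with no stoichiometry, flux balance, or cost. Network
expansion computes the least fixpoint of this firing rule from a set of seed
nutrients; the set of compounds synthesized by fired reactions is the *scope*.

By default the reported scope excludes seed compounds unless a fired reaction
regenerates them (the expansion infers "other reachable compounds"); pass
``include_seeds=True`` for the inclusive variant.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import libsbml

logger = logging.getLogger("metapot")

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "DirectedReactionSet",
    "ParseReport",
    "NetworkParseError",
    "parse_sbml",
    "write_sbml",
    "parse_network_table",
    "write_network_table",
    "read_seed_file",
    "write_seed_file",
    "directed_view",
    "expansion_scope",
]


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed into a valid model."""


@dataclass(frozen=True)
class Metabolite:
    """A compound node, identified by an exact database-style string id."""

    id: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be nonempty")


@dataclass(frozen=True)
class Reaction:
    """A Boolean reaction: reactant set -> product set, optionally reversible.

    Stoichiometric coefficients are discarded; a metabolite may appear on both
    sides. Reactions missing either side are rejected at construction — an
    empty reactant set would silently inject its products into every scope.
    """

    id: str
    reactants: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be nonempty")
        if not self.reactants or not self.products:
            raise ValueError(
                f"reaction {self.id!r}: reactants and products must both be nonempty"
            )
        object.__setattr__(self, "reactants", frozenset(self.reactants))
        object.__setattr__(self, "products", frozenset(self.products))


@dataclass
class MetabolicNetwork:
    """A named set of reactions; the metabolite universe is derived from them."""

    id: str
    reactions: tuple[Reaction, ...] = ()

    def __post_init__(self) -> None:
        self.reactions = tuple(self.reactions)

    @property
    def metabolites(self) -> frozenset[str]:
        ids: set[str] = set()
        for r in self.reactions:
            ids.update(r.reactants)
            ids.update(r.products)
        return frozenset(ids)

    def __len__(self) -> int:
        return len(self.reactions)

    def reaction_set(self) -> frozenset[tuple]:
        """Content-based identity, ignoring reaction ids and order."""
        return frozenset(
            (r.reactants, r.products, r.reversible) for r in self.reactions
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return self.id == other.id and self.reaction_set() == other.reaction_set()


@dataclass
class ParseReport:
    """Bookkeeping from a parse: what was skipped or dropped and why."""

    source: str = ""
    n_reactions: int = 0
    skipped_reactions: list[str] = field(default_factory=list)
    dropped_species: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "n_reactions": self.n_reactions,
                "skipped_reactions": self.skipped_reactions,
                "dropped_species": self.dropped_species,
                "warnings": self.warnings,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Directed view
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DirectedReactionSet:
    """Directed firing rules derived from a network.

    Each irreversible reaction yields one (inputs, outputs) rule; each
    reversible reaction yields two, forward and swapped, which can fire
    independently. Rule order follows reaction order, so the derivation is
    deterministic.
    """

    rules: tuple[tuple[frozenset[str], frozenset[str]], ...]

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[tuple[frozenset[str], frozenset[str]]]:
        return iter(self.rules)


def directed_view(network: MetabolicNetwork) -> DirectedReactionSet:
    """Split reactions into directed rules (two per reversible reaction)."""
    rules: list[tuple[frozenset[str], frozenset[str]]] = []
    for r in network.reactions:
        rules.append((r.reactants, r.products))
        if r.reversible:
            rules.append((r.products, r.reactants))
    return DirectedReactionSet(tuple(rules))


# ---------------------------------------------------------------------------
# Network expansion
# ---------------------------------------------------------------------------


def expansion_scope(
    network: MetabolicNetwork | DirectedReactionSet | Sequence[Reaction],
    seeds: Iterable[str],
    *,
    include_seeds: bool = False,
) -> frozenset[str]:
    """Least-fixpoint Boolean expansion of ``seeds`` through the network.

    A directed rule fires once all its inputs are available; its outputs then
    become available. The returned scope is the set of metabolites synthesized
    by fired rules — seeds are excluded unless some fired rule regenerates
    them (``include_seeds=True`` returns scope ∪ seeds instead). Seeds absent
    from the network are inert. The result is monotone in both seeds and
    reactions and independent of reaction order.

    Runs in O(sum of rule input sizes) via a counting propagation: each rule
    tracks how many inputs are still missing and fires when the count hits 0.
    """
    if isinstance(network, MetabolicNetwork):
        rules = directed_view(network).rules
    elif isinstance(network, DirectedReactionSet):
        rules = network.rules
    else:
        rules = directed_view(MetabolicNetwork("_adhoc", tuple(network))).rules

    seeds = frozenset(seeds)
    missing = [len(inp) for inp, _ in rules]
    needs: dict[str, list[int]] = defaultdict(list)
    for i, (inp, _) in enumerate(rules):
        for m in inp:
            needs[m].append(i)

    available: set[str] = set()
    produced: set[str] = set()
    stack: list[int] = [i for i, n in enumerate(missing) if n == 0]

    def make_available(m: str) -> None:
        if m in available:
            return
        available.add(m)
        for i in needs.get(m, ()):
            missing[i] -= 1
            if missing[i] == 0:
                stack.append(i)

    for s in seeds:
        make_available(s)
    while stack:
        i = stack.pop()
        for out in rules[i][1]:
            produced.add(out)
            make_available(out)

    if include_seeds:
        return frozenset(produced | seeds)
    return frozenset(produced)


# ---------------------------------------------------------------------------
# SBML I/O (Level 3 subset: species, reactions, reversible attribute)
# ---------------------------------------------------------------------------

# Database-style metabolite ids (MetaCyc frames like "MG+2", "CL-",
# "CARBON-DIOXIDE") are not legal SBML SIds. Characters outside
# [a-zA-Z0-9_] are escaped as __{ascii}__ on write and unescaped on read,
# the convention SBML-facing toolkits use; a leading digit is escaped too.

_SID_BAD = re.compile(r"[^0-9a-zA-Z_]")
_SID_ESC = re.compile(r"__(\d+)__")


def _encode_sid(raw: str) -> str:
    sid = _SID_BAD.sub(lambda m: f"__{ord(m.group(0))}__", raw)
    if sid[0].isdigit():
        sid = f"__{ord(sid[0])}__" + sid[1:]
    return sid


def _decode_sid(sid: str) -> str:
    return _SID_ESC.sub(lambda m: chr(int(m.group(1))), sid)


def _reaction_from_sbml(rxn: libsbml.Reaction) -> Reaction | None:
    reactants = frozenset(
        _decode_sid(ref.getSpecies())
        for ref in rxn.getListOfReactants()
        if ref.getSpecies()
    )
    products = frozenset(
        _decode_sid(ref.getSpecies())
        for ref in rxn.getListOfProducts()
        if ref.getSpecies()
    )
    if not reactants or not products:
        return None
    return Reaction(
        _decode_sid(rxn.getId()), reactants, products, bool(rxn.getReversible())
    )


def parse_sbml(path: str | Path) -> tuple[MetabolicNetwork, ParseReport]:
    """Read a metabolic network from SBML.

    Every SBML reaction with both sides nonempty maps to one :class:`Reaction`;
    reactions lacking a side are skipped with a warning and recorded in the
    parse report. Species never referenced by a kept reaction are dropped (the
    model's metabolite set derives from reactions); boundary and exchange
    species are ordinary metabolites here.
    """
    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise NetworkParseError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    model = doc.getModel()
    if model is None:
        raise NetworkParseError(f"{path}: SBML file contains no model")

    report = ParseReport(source=str(path))
    reactions: list[Reaction] = []
    for rxn in model.getListOfReactions():
        parsed = _reaction_from_sbml(rxn)
        if parsed is None:
            msg = f"reaction {rxn.getId()!r} has an empty reactant or product list; skipped"
            warnings.warn(msg, stacklevel=2)
            report.skipped_reactions.append(rxn.getId())
            report.warnings.append(msg)
            continue
        reactions.append(parsed)

    net = MetabolicNetwork(_decode_sid(model.getId()) or path.stem, tuple(reactions))
    referenced = net.metabolites
    n_declared = model.getNumSpecies()
    report.dropped_species = sum(
        1 for sp in model.getListOfSpecies() if _decode_sid(sp.getId()) not in referenced
    )
    if report.dropped_species:
        logger.info(
            "%s: dropped %d of %d species unreferenced by any reaction",
            path,
            report.dropped_species,
            n_declared,
        )
    report.n_reactions = len(reactions)
    return net, report


def write_sbml(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the network as minimal SBML Level 3 Version 1."""
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(_encode_sid(network.id))
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for mid in sorted(network.metabolites):
        sp = model.createSpecies()
        sp.setId(_encode_sid(mid))
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    for r in sorted(network.reactions, key=lambda r: r.id):
        rxn = model.createReaction()
        rxn.setId(_encode_sid(r.id))
        rxn.setReversible(r.reversible)
        rxn.setFast(False)
        for mid in sorted(r.reactants):
            ref = rxn.createReactant()
            ref.setSpecies(_encode_sid(mid))
            ref.setConstant(True)
        for mid in sorted(r.products):
            ref = rxn.createProduct()
            ref.setSpecies(_encode_sid(mid))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(Path(path)))


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_REV_TOKENS = {
    "rev": True,
    "reversible": True,
    "true": True,
    "1": True,
    "irrev": False,
    "irreversible": False,
    "false": False,
    "0": False,
}


def parse_network_table(path: str | Path) -> tuple[MetabolicNetwork, ParseReport]:
    """Read the tab-separated dialect: id, reactants, products, reversibility.

    Reactant and product fields are comma-joined metabolite ids. Lines
    beginning with ``#`` are comments. Duplicate reaction ids and unknown
    reversibility tokens are errors; rows with an empty side are skipped with
    a warning, mirroring the SBML parser's contract.
    """
    path = Path(path)
    report = ParseReport(source=str(path))
    reactions: list[Reaction] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            rid, reac_f, prod_f, rev_f = (f.strip() for f in fields)
            if rid in seen:
                raise NetworkParseError(f"{path}:{lineno}: duplicate reaction id {rid!r}")
            seen.add(rid)
            token = rev_f.lower()
            if token not in _REV_TOKENS:
                raise NetworkParseError(
                    f"{path}:{lineno}: unknown reversibility token {rev_f!r}"
                )
            reactants = frozenset(m.strip() for m in reac_f.split(",") if m.strip())
            products = frozenset(m.strip() for m in prod_f.split(",") if m.strip())
            if not reactants or not products:
                msg = f"reaction {rid!r} has an empty reactant or product field; skipped"
                warnings.warn(msg, stacklevel=2)
                report.skipped_reactions.append(rid)
                report.warnings.append(msg)
                continue
            reactions.append(Reaction(rid, reactants, products, _REV_TOKENS[token]))
    report.n_reactions = len(reactions)
    return MetabolicNetwork(path.stem, tuple(reactions)), report


def write_network_table(network: MetabolicNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id\treactants\tproducts\treversibility\n")
        for r in sorted(network.reactions, key=lambda r: r.id):
            fh.write(
                "\t".join(
                    [
                        r.id,
                        ",".join(sorted(r.reactants)),
                        ",".join(sorted(r.products)),
                        "rev" if r.reversible else "irrev",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Seed files
# ---------------------------------------------------------------------------


def read_seed_file(path: str | Path) -> frozenset[str]:
    """Plain-text seed list: one metabolite id per line, ``#`` comments."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line)
    return frozenset(ids)


def write_seed_file(seeds: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mid in sorted(seeds):
            fh.write(mid + "\n")
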