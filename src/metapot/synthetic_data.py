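"""Synthetic worlds with ground-truth manifests for the whole pipeline.

A *world* emulates the study design the pipeline assumes: several sites, each
with a handful of organism (MAG-like) networks whose union approximates the
site's metagenome network plus extra unbinned reactions; planted cross-feeding
pathways split across organisms (cooperation-only products); planted redundant
producers (interchangeable organisms for minimal-community selection); planted
gap-fill-like artifacts reachable only at genome-resolved scale; and an
environmental table whose planted variables track the site-presence pattern of
chosen metabolite groups at a configured effect size.

Every planted claim is written to a manifest whose expected scopes are derived
*constructively* from pathway bookkeeping (a pathway's metabolites are
producible wherever the pathway is present and its root nutrient is in the
seed condition) — independent of the expansion engine, so the manifest can
serve as an oracle for it.

Worlds are abstract: metabolite ids are opaque (``M0042``), rooted in the
packaged basal medium so that all five canonical conditions apply.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import ConditionLibrary, SeedCondition, canonical_library
from .community_scope import SystemSpec
from .network_model import MetabolicNetwork, Reaction, parse_sbml, write_sbml

__all__ = [
    "WorldConfig",
    "World",
    "build_world",
    "generate_world",
    "load_world",
    "make_fixture_suite",
]

ENV_VARIABLE_NAMES = [
    "pH", "EC", "OM", "N", "NH4", "NO3", "P", "K", "Mg",
    "Ca", "Cu", "Fe", "Zn", "Mn", "B", "S", "Na",
]


@dataclass
class WorldConfig:
    """Generator knobs; defaults are the package's study conditions.

    ``organisms_per_site`` and ``pathway_length`` are inclusive ranges.
    ``universe_size`` caps the abstract metabolite vocabulary; a configuration
    that needs more ids than that is unsatisfiable and rejected at generation.
    """

    n_sites: int = 6
    organisms_per_site: tuple[int, int] = (8, 20)
    universe_size: int = 300
    pathway_length: tuple[int, int] = (2, 6)
    crossfeeding_split: float = 0.3
    redundancy_level: int = 2
    n_env_variables: int = 17
    n_planted_associated_groups: int = 4
    association_effect_size: float = 0.6
    response_noise_sd: float = 0.2
    unbinned_reaction_fraction: float = 0.2
    mag_only_artifact_count: int = 5
    seed: int = 0
    # structural knobs beyond the headline design
    n_pathways_per_site: int = 7
    n_shared_pathways: int = 6
    condition_rooted_fraction: float = 0.25
    n_essential_targets: int = 3
    n_redundant_targets: int = 2
    reversible_prob: float = 0.2
    cosubstrate_prob: float = 0.3

    def validate(self) -> None:
        counts = {
            "n_sites": self.n_sites,
            "universe_size": self.universe_size,
            "redundancy_level": self.redundancy_level,
            "n_env_variables": self.n_env_variables,
            "n_pathways_per_site": self.n_pathways_per_site,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, p in {
            "crossfeeding_split": self.crossfeeding_split,
            "unbinned_reaction_fraction": self.unbinned_reaction_fraction,
            "condition_rooted_fraction": self.condition_rooted_fraction,
            "reversible_prob": self.reversible_prob,
            "cosubstrate_prob": self.cosubstrate_prob,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.organisms_per_site
        carriers = self.n_essential_targets + self.n_redundant_targets * self.redundancy_level
        if carriers > lo:
            raise ValueError(
                f"target carriers ({carriers}) exceed minimum organisms per site ({lo})"
            )
        if self.n_essential_targets + self.n_redundant_targets > self.n_pathways_per_site:
            raise ValueError("more target pathways than pathways per site")
        if self.n_planted_associated_groups > self.n_env_variables:
            raise ValueError("more planted associations than environmental variables")


@dataclass
class _Pathway:
    id: str
    category: str  # shared | planted | site | unbinned | artifact
    root: str
    metabolites: list[str]
    reactions: list[Reaction]
    # presence: site -> {"metagenome": bool, "organisms": {org: [reaction ids]}}
    presence: dict = field(default_factory=dict)
    split_info: dict = field(default_factory=dict)


@dataclass
class World:
    """In-memory world: networks, environment, and the ground-truth manifest."""

    config: WorldConfig
    sites: list[str]
    organisms: dict[str, list[str]]
    member_networks: dict[str, dict[str, MetabolicNetwork]]
    metagenome_networks: dict[str, MetabolicNetwork]
    env: pd.DataFrame
    conditions: ConditionLibrary
    manifest: dict

    def systems(self) -> list[SystemSpec]:
        out: list[SystemSpec] = []
        for site in self.sites:
            out.append(SystemSpec(site, "metagenome", (self.metagenome_networks[site],)))
            out.append(
                SystemSpec(
                    site,
                    "genome_resolved",
                    tuple(self.member_networks[site][o] for o in self.organisms[site]),
                )
            )
        return out


def _balanced_patterns(rng: np.random.Generator, n_sites: int, n: int) -> list[tuple[int, ...]]:
    """Distinct site-presence patterns with floor(n_sites/2) sites on.

    Patterns are also pairwise non-complementary: a balanced pattern and its
    complement are perfectly anti-correlated at site level, so planting both
    would make the two associations unidentifiable (any fit can swap them
    with flipped sign) and the manifest's claims unverifiable.
    """
    n_on = n_sites // 2
    patterns: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    guard = 0
    while len(patterns) < n:
        idx = rng.choice(n_sites, size=n_on, replace=False)
        pat = tuple(1 if i in set(idx.tolist()) else 0 for i in range(n_sites))
        comp = tuple(1 - v for v in pat)
        if pat not in seen and comp not in seen:
            seen.add(pat)
            patterns.append(pat)
        guard += 1
        if guard > 10_000:
            raise ValueError("cannot draw enough distinct site patterns")
    return patterns


def build_world(config: WorldConfig) -> World:
    """Generate a world in memory; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    library = canonical_library()
    basal = sorted(library["basal_medium"].seeds)
    non_basal = [c for c in library.names() if c != "basal_medium"]
    additions = {
        name: sorted(library[name].seeds - library["basal_medium"].seeds)
        for name in non_basal
    }

    sites = [f"S{i}" for i in range(1, config.n_sites + 1)]
    lo, hi = config.organisms_per_site
    organisms = {
        site: [f"{site}_MAG_{j:02d}" for j in range(1, int(rng.integers(lo, hi + 1)) + 1)]
        for site in sites
    }

    met_counter = 0

    def new_met() -> str:
        nonlocal met_counter
        met_counter += 1
        if met_counter > config.universe_size:
            raise ValueError(
                f"universe_size={config.universe_size} exhausted; "
                "configuration is unsatisfiable"
            )
        return f"M{met_counter:04d}"

    pathways: list[_Pathway] = []
    pw_counter = 0

    def build_chain(category: str, root: str, length: int | None = None) -> _Pathway:
        nonlocal pw_counter
        pw_counter += 1
        pid = f"P{pw_counter:04d}"
        if length is None:
            length = int(rng.integers(config.pathway_length[0], config.pathway_length[1] + 1))
        mets = [new_met() for _ in range(length)]
        reactions: list[Reaction] = []
        prev = root
        for j, m in enumerate(mets):
            inputs = {prev}
            if j > 0 and rng.random() < config.cosubstrate_prob:
                inputs.add(basal[int(rng.integers(len(basal)))])
            # the first step and co-substrate steps stay irreversible: their
            # reverse rules would synthesize seed compounds
            reversible = (
                j > 0 and len(inputs) == 1 and rng.random() < config.reversible_prob
            )
            reactions.append(Reaction(f"{pid}_r{j}", frozenset(inputs), frozenset({m}), reversible))
            prev = m
        return _Pathway(pid, category, root, mets, reactions)

    def pick_root() -> str:
        if rng.random() < config.condition_rooted_fraction:
            cond = non_basal[int(rng.integers(len(non_basal)))]
            pool = additions[cond]
        else:
            pool = basal
        return pool[int(rng.integers(len(pool)))]

    # --- shared (core) pathways: every site, both scales -------------------
    for _ in range(config.n_shared_pathways):
        pw = build_chain("shared", basal[int(rng.integers(len(basal)))])
        for site in sites:
            org = organisms[site][int(rng.integers(len(organisms[site])))]
            pw.presence[site] = {"metagenome": True, "organisms": {org: pw.reactions}}
        pathways.append(pw)

    # --- planted association pathways: balanced site patterns --------------
    patterns = _balanced_patterns(rng, config.n_sites, config.n_planted_associated_groups)
    planted: list[dict] = []
    env_vars = list(ENV_VARIABLE_NAMES[: config.n_env_variables])
    while len(env_vars) < config.n_env_variables:
        env_vars.append(f"X{len(env_vars) + 1}")
    planted_vars = [
        env_vars[i]
        for i in sorted(
            rng.choice(config.n_env_variables, size=config.n_planted_associated_groups, replace=False).tolist()
        )
    ]
    for pat, var in zip(patterns, planted_vars):
        pw = build_chain("planted", basal[int(rng.integers(len(basal)))], length=3)
        for site, on in zip(sites, pat):
            if on:
                org = organisms[site][int(rng.integers(len(organisms[site])))]
                pw.presence[site] = {"metagenome": True, "organisms": {org: pw.reactions}}
        pathways.append(pw)
        planted.append(
            {
                "variable": var,
                "pattern": {site: int(on) for site, on in zip(sites, pat)},
                "sign": int(rng.choice([-1, 1])),
                "effect_size": config.association_effect_size,
                "group_metabolites": list(pw.metabolites),
                "pathway": pw.id,
            }
        )

    # --- per-site pathways: targets first, then split/regular --------------
    mincom_truth: dict[str, dict] = {}
    cooperation: dict[str, list[str]] = {site: [] for site in sites}
    for site in sites:
        orgs = organisms[site]
        order = [orgs[i] for i in rng.permutation(len(orgs))]
        ess_carriers = order[: config.n_essential_targets]
        red_chunks = [
            order[
                config.n_essential_targets + i * config.redundancy_level :
                config.n_essential_targets + (i + 1) * config.redundancy_level
            ]
            for i in range(config.n_redundant_targets)
        ]
        targets: list[str] = []
        classes: list[list[str]] = []
        for org in ess_carriers:
            pw = build_chain("site", basal[int(rng.integers(len(basal)))])
            pw.presence[site] = {"metagenome": True, "organisms": {org: pw.reactions}}
            pathways.append(pw)
            targets.append(pw.metabolites[-1])
        for chunk in red_chunks:
            pw = build_chain("site", basal[int(rng.integers(len(basal)))])
            pw.presence[site] = {
                "metagenome": True,
                "organisms": {org: pw.reactions for org in chunk},
            }
            pathways.append(pw)
            targets.append(pw.metabolites[-1])
            classes.append(sorted(chunk))
        mincom_truth[site] = {
            "targets": sorted(targets),
            "k": config.n_essential_targets + config.n_redundant_targets,
            "essential": sorted(ess_carriers),
            "classes": classes,
            "n_solutions": config.redundancy_level ** config.n_redundant_targets,
        }

        n_rest = config.n_pathways_per_site - config.n_essential_targets - config.n_redundant_targets
        for _ in range(n_rest):
            if rng.random() < config.crossfeeding_split:
                pw = build_chain("site", basal[int(rng.integers(len(basal)))])
                cut = int(rng.integers(1, len(pw.metabolites)))  # head keeps mets[:cut]
                head, tail = [orgs[i] for i in rng.choice(len(orgs), size=2, replace=False)]
                pw.presence[site] = {
                    "metagenome": True,
                    "organisms": {head: pw.reactions[:cut], tail: pw.reactions[cut:]},
                }
                pw.split_info = {"site": site, "head": head, "tail": tail, "cut": cut}
                cooperation[site].extend(pw.metabolites[cut:])
                pathways.append(pw)
            else:
                pw = build_chain("site", pick_root())
                org = orgs[int(rng.integers(len(orgs)))]
                pw.presence[site] = {"metagenome": True, "organisms": {org: pw.reactions}}
                pathways.append(pw)

    # --- unbinned pathways: metagenome only --------------------------------
    n_unbinned = max(1, round(config.unbinned_reaction_fraction * config.n_pathways_per_site))
    unbinned_ids: dict[str, list[str]] = {site: [] for site in sites}
    for site in sites:
        for _ in range(n_unbinned):
            pw = build_chain("unbinned", pick_root())
            pw.presence[site] = {"metagenome": True, "organisms": {}}
            pathways.append(pw)
            unbinned_ids[site].extend(pw.metabolites)

    # --- gap-fill-like artifacts: one organism, never the metagenome -------
    artifacts: list[dict] = []
    for i in range(1, config.mag_only_artifact_count + 1):
        aid = f"ART{i:03d}"
        site = sites[int(rng.integers(len(sites)))]
        org = organisms[site][int(rng.integers(len(organisms[site])))]
        substrate = basal[int(rng.integers(len(basal)))]
        rxn = Reaction(f"GF_{aid}", frozenset({substrate}), frozenset({aid}), False)
        pw = _Pathway(f"PA{i:03d}", "artifact", substrate, [aid], [rxn])
        pw.presence[site] = {"metagenome": False, "organisms": {org: [rxn]}}
        pathways.append(pw)
        artifacts.append({"id": aid, "site": site, "organism": org})

    # --- assemble networks --------------------------------------------------
    member_networks: dict[str, dict[str, MetabolicNetwork]] = {}
    metagenome_networks: dict[str, MetabolicNetwork] = {}
    for site in sites:
        per_org: dict[str, list[Reaction]] = {org: [] for org in organisms[site]}
        metag: list[Reaction] = []
        for pw in pathways:
            pres = pw.presence.get(site)
            if not pres:
                continue
            if pres["metagenome"]:
                metag.extend(pw.reactions)
            for org, rxns in pres["organisms"].items():
                per_org[org].extend(rxns)
        member_networks[site] = {
            org: MetabolicNetwork(org, tuple(sorted(rxns, key=lambda r: r.id)))
            for org, rxns in per_org.items()
        }
        metagenome_networks[site] = MetabolicNetwork(
            f"{site}_metagenome", tuple(sorted(metag, key=lambda r: r.id))
        )

    # --- constructive expected scopes ---------------------------------------
    expected: dict[str, set[str]] = {}
    for site in sites:
        for scale in ("metagenome", "genome_resolved"):
            for cond in library:
                expected[f"{site}|{scale}|{cond.name}"] = set()
    for pw in pathways:
        for site, pres in pw.presence.items():
            scales = []
            if pres["metagenome"]:
                scales.append("metagenome")
            if pres["organisms"]:
                scales.append("genome_resolved")
            for scale in scales:
                for cond in library:
                    if pw.root in cond.seeds:
                        expected[f"{site}|{scale}|{cond.name}"].update(pw.metabolites)

    # --- abundances ----------------------------------------------------------
    abundances: dict[str, dict[str, float]] = {}
    for site in sites:
        total = float(rng.uniform(10.0, 20.0))
        w = rng.lognormal(0.0, 1.0, size=len(organisms[site]))
        pct = total * w / w.sum()
        abundances[site] = {
            org: round(float(p), 4) for org, p in zip(organisms[site], pct)
        }

    # --- environmental table -------------------------------------------------
    planted_by_var = {p["variable"]: p for p in planted}
    env_data: dict[str, np.ndarray] = {}
    for var in env_vars:
        if var in planted_by_var:
            p = planted_by_var[var]
            pat = np.array([p["pattern"][s] for s in sites], dtype=float)
            z = (pat - pat.mean()) / pat.std()
            env_data[var] = (
                p["sign"] * config.association_effect_size * z
                + rng.normal(0.0, config.response_noise_sd, size=len(sites))
            )
        else:
            env_data[var] = rng.normal(0.0, 1.0, size=len(sites))
    env = pd.DataFrame(env_data, index=pd.Index(sites, name="site"))

    manifest = {
        "config": asdict(config),
        "sites": sites,
        "organisms": organisms,
        "env_variables": env_vars,
        "expected_scopes": {k: sorted(v) for k, v in sorted(expected.items())},
        "cooperation_only": {site: sorted(set(cooperation[site])) for site in sites},
        "unbinned_metabolites": {site: sorted(set(unbinned_ids[site])) for site in sites},
        "artifacts": artifacts,
        "mincom": mincom_truth,
        "associations": planted,
        "abundances": abundances,
        "n_metabolites_used": met_counter,
        "condition_library": "metapot.data/conditions.yaml",
    }
    return World(
        config=config,
        sites=sites,
        organisms=organisms,
        member_networks=member_networks,
        metagenome_networks=metagenome_networks,
        env=env,
        conditions=library,
        manifest=manifest,
    )


def generate_world(config: WorldConfig, out_dir: str | Path) -> tuple[Path, dict]:
    """Write a world to disk (SBML networks, env TSV, manifest JSON).

    Layout: ``<out>/<site>/<organism>.sbml``, ``<out>/<site>/metagenome.sbml``,
    ``<out>/env_table.tsv``, ``<out>/manifest.json``. Regeneration with the
    same config and seed is byte-identical.
    """
    world = build_world(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for site in world.sites:
        site_dir = out / site
        site_dir.mkdir(exist_ok=True)
        for org in world.organisms[site]:
            write_sbml(world.member_networks[site][org], site_dir / f"{org}.sbml")
        write_sbml(world.metagenome_networks[site], site_dir / "metagenome.sbml")
    world.env.to_csv(out / "env_table.tsv", sep="\t", float_format="%.12g")
    (out / "manifest.json").write_text(
        json.dumps(world.manifest, indent=2, sort_keys=True) + "\n"
    )
    return out, world.manifest


def load_world(world_dir: str | Path) -> World:
    """Reload a generated world from disk through the SBML parser."""
    world_dir = Path(world_dir)
    manifest = json.loads((world_dir / "manifest.json").read_text())
    config = WorldConfig(**{
        **manifest["config"],
        "organisms_per_site": tuple(manifest["config"]["organisms_per_site"]),
        "pathway_length": tuple(manifest["config"]["pathway_length"]),
    })
    sites = manifest["sites"]
    organisms = manifest["organisms"]
    member_networks: dict[str, dict[str, MetabolicNetwork]] = {}
    metagenome_networks: dict[str, MetabolicNetwork] = {}
    for site in sites:
        member_networks[site] = {}
        for org in organisms[site]:
            net, _ = parse_sbml(world_dir / site / f"{org}.sbml")
            member_networks[site][org] = net
        metagenome_networks[site], _ = parse_sbml(world_dir / site / "metagenome.sbml")
    env = pd.read_csv(world_dir / "env_table.tsv", sep="\t", index_col="site")
    return World(
        config=config,
        sites=sites,
        organisms=organisms,
        member_networks=member_networks,
        metagenome_networks=metagenome_networks,
        env=env,
        conditions=canonical_library(),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Curated small fixtures with hand-checked expectations
# ---------------------------------------------------------------------------


def _rxn(rid: str, inputs: set[str], outputs: set[str], rev: bool = False) -> Reaction:
    return Reaction(rid, frozenset(inputs), frozenset(outputs), rev)


def make_fixture_suite() -> dict[str, dict]:
    """Tiny hand-written instances with stored expected outputs.

    Keys: ``linear_chain``, ``blocked_conjunction``, ``handoff_pair``,
    ``interchangeable_producers``, ``enumeration_12``. Expected values were
    derived by hand (and double-checked by exhaustive search in the test
    suite, which re-verifies them at run time rather than trusting them).
    """
    cond_a = SeedCondition("seed_a", frozenset({"A"}))

    chain = MetabolicNetwork("chain", (_rxn("r1", {"A"}, {"B"}), _rxn("r2", {"B"}, {"C"})))
    blocked = MetabolicNetwork("blocked", (_rxn("r1", {"A", "X"}, {"B"}),))
    handoff = SystemSpec(
        "toy",
        "genome_resolved",
        (
            MetabolicNetwork("m1", (_rxn("r1", {"A"}, {"B"}),)),
            MetabolicNetwork("m2", (_rxn("r2", {"B"}, {"C"}),)),
        ),
    )

    # 3 unique producers + one target with 2 interchangeable producers
    ess = [
        MetabolicNetwork(f"e{i}", (_rxn(f"e{i}_r", {"A"}, {f"t{i}"}),)) for i in (1, 2, 3)
    ]
    pair = [
        MetabolicNetwork(f"p{i}", (_rxn(f"p{i}_r", {"A"}, {"t4"}),)) for i in (1, 2)
    ]
    interchangeable = SystemSpec("toy", "genome_resolved", tuple(ess + pair))

    # 12 members: 2 essential, one OR-class of 3, one OR-class of 2, 5 inert
    e12 = [MetabolicNetwork(f"e{i}", (_rxn(f"e{i}_r", {"A"}, {f"t{i}"}),)) for i in (1, 2)]
    cls3 = [MetabolicNetwork(f"a{i}", (_rxn(f"a{i}_r", {"A"}, {"t3"}),)) for i in (1, 2, 3)]
    cls2 = [MetabolicNetwork(f"b{i}", (_rxn(f"b{i}_r", {"A"}, {"t4"}),)) for i in (1, 2)]
    inert = [
        MetabolicNetwork(f"z{i}", (_rxn(f"z{i}_r", {f"u{i}"}, {f"v{i}"}),))
        for i in (1, 2, 3, 4, 5)
    ]
    enum12 = SystemSpec("toy", "genome_resolved", tuple(e12 + cls3 + cls2 + inert))

    return {
        "linear_chain": {
            "network": chain,
            "condition": cond_a,
            "expected_scope": frozenset({"B", "C"}),
        },
        "blocked_conjunction": {
            "network": blocked,
            "condition": cond_a,
            "expected_scope": frozenset(),
        },
        "handoff_pair": {
            "system": handoff,
            "condition": cond_a,
            "expected_community": frozenset({"B", "C"}),
            "expected_members": {"m1": frozenset({"B"}), "m2": frozenset()},
            "expected_cooperation_only": frozenset({"C"}),
        },
        "interchangeable_producers": {
            "system": interchangeable,
            "condition": cond_a,
            "targets": frozenset({"t1", "t2", "t3", "t4"}),
            "expected_k": 4,
            "expected_n_solutions": 2,
            "expected_essential": frozenset({"e1", "e2", "e3"}),
            "expected_alternative": frozenset({"p1", "p2"}),
            "expected_classes": [frozenset({"p1", "p2"})],
        },
        "enumeration_12": {
            "system": enum12,
            "condition": cond_a,
            "targets": frozenset({"t1", "t2", "t3", "t4"}),
            "expected_k": 4,
            "expected_n_solutions": 6,
            "expected_essential": frozenset({"e1", "e2"}),
            "expected_alternative": frozenset({"a1", "a2", "a3", "b1", "b2"}),
            "expected_classes": [
                frozenset({"a1", "a2", "a3"}),
                frozenset({"b1", "b2"}),
            ],
        },
    }
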