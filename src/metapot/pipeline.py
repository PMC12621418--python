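"""End-to-end orchestration: grid -> filter -> collapse -> association ->
key-metabolite selection -> target filtering -> minimal communities.

A run is fully described by a :class:`PipelineConfig`; identical configs (and
thus identical config hashes) reproduce identical artifacts, with all
randomness seeded from the config. Artifacts land in a fixed layout under the
output directory and the run report records every stage's headline numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .conditions import ConditionLibrary, canonical_library, load_condition_library
from .env_association import (
    build_design,
    cluster_variables,
    fit_all_variables,
    select_key_metabolites,
)
from .minimal_communities import (
    enumerate_solutions,
    filter_targets,
    substitutable_groups,
)
from .producibility_matrix import (
    collapse_groups,
    core_metabolites,
    filter_gapfill_artifacts,
    groups_table,
    run_grid,
)
from .synthetic_data import load_world

logger = logging.getLogger("metapot")

__all__ = ["PipelineConfig", "RunReport", "run_all"]


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for a full run.

    ``world_dir`` points at a generated (or equivalently laid-out) world:
    per-site directories of member SBML files plus ``metagenome.sbml``, an
    ``env_table.tsv``, and a manifest. ``condition_library`` defaults to the
    packaged five-condition library. Parameters default to the study values:
    elastic-net mixing 0.85, key-metabolite threshold 0.3, basal medium for
    minimal communities.
    """

    world_dir: str
    out_dir: str
    condition_library: str | None = None
    conditions: list[str] | None = None
    mincom_condition: str = "basal_medium"
    mixing: float = 0.85
    key_threshold: float = 0.3
    design_unit: str = "simulation"
    solution_cap: int = 10_000
    include_seeds: bool = False
    n_variable_clusters: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.world_dir).is_dir():
            raise FileNotFoundError(f"world_dir not found: {self.world_dir}")
        if self.condition_library and not Path(self.condition_library).is_file():
            raise FileNotFoundError(
                f"condition_library not found: {self.condition_library}"
            )
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError(f"mixing must be in [0, 1], got {self.mixing}")
        if self.key_threshold < 0:
            raise ValueError(f"key_threshold must be >= 0, got {self.key_threshold}")
        if self.design_unit not in {"simulation", "site"}:
            raise ValueError(f"unknown design_unit {self.design_unit!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def hash(self) -> str:
        """Hash of input *content* and parameters.

        The world directory contributes by file content, not by path, and the
        output location is excluded — so one set of inputs and parameters
        hashes alike wherever it sits, and the hash fully determines the
        artifacts of a run.
        """
        payload = asdict(self)
        payload.pop("out_dir")
        world = Path(payload.pop("world_dir"))
        tree = hashlib.sha256()
        if world.is_dir():
            for p in sorted(world.rglob("*")):
                if p.is_file():
                    tree.update(p.relative_to(world).as_posix().encode())
                    tree.update(p.read_bytes())
        payload["world_content"] = tree.hexdigest()
        if self.condition_library:
            payload["condition_library"] = hashlib.sha256(
                Path(self.condition_library).read_bytes()
            ).hexdigest()
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    stages: dict = field(default_factory=dict)
    warnings: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )


def _load_library(config: PipelineConfig) -> ConditionLibrary:
    if config.condition_library:
        return load_condition_library(config.condition_library)
    return canonical_library()


def run_all(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and write all artifacts.

    A stage failure aborts the run with the stage name and the offending
    input in the exception message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash())
    t0 = time.time()

    def stage(name: str):
        logger.info("stage %s starting (t=%.1fs)", name, time.time() - t0)

    try:
        stage("load")
        world = load_world(config.world_dir)
        library = _load_library(config)
        cond_names = config.conditions or library.names()
        conditions = [library[n] for n in cond_names]
        systems = world.systems()
        report.stages["load"] = {
            "n_sites": len(world.sites),
            "n_systems": len(systems),
            "n_conditions": len(conditions),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed on {config.world_dir}: {exc}") from exc

    try:
        stage("grid")
        matrix = run_grid(systems, conditions, include_seeds=config.include_seeds)
        report.stages["grid"] = {
            "n_cells": matrix.n_simulations,
            "n_metabolites": matrix.n_metabolites,
            "scope_sizes": {
                c: int(matrix.data[c].sum()) for c in matrix.data.columns
            },
            "seed_convention": matrix.seed_convention,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'grid' failed: {exc}") from exc

    try:
        stage("filter")
        matrix, removed = filter_gapfill_artifacts(matrix)
        matrix.save(out)
        pd.Series(removed, name="metabolite").to_csv(
            out / "removed_artifacts.tsv", sep="\t", index=False
        )
        report.stages["filter"] = {
            "n_removed": len(removed),
            "n_metabolites_kept": matrix.n_metabolites,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc

    try:
        stage("collapse")
        groups = collapse_groups(matrix)
        groups_table(groups).to_csv(out / "groups.tsv", sep="\t")
        report.stages["collapse"] = {
            "n_groups": len(groups),
            "core_metagenome": len(core_metabolites(matrix, "metagenome")),
            "core_genome_resolved": len(core_metabolites(matrix, "genome_resolved")),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'collapse' failed: {exc}") from exc

    try:
        stage("associate")
        design = build_design(groups, matrix, world.env, unit=config.design_unit)
        results = fit_all_variables(design, mixing=config.mixing, seed=config.seed)
        coef = pd.DataFrame({v: r.coefficients for v, r in results.items()})
        coef.to_csv(out / "coefficients.tsv", sep="\t", index_label="group")
        keys = select_key_metabolites(results, groups, config.key_threshold)
        keys.coefficient_table().to_csv(out / "key_groups.tsv", sep="\t", index=False)
        pd.Series(sorted(keys.key_metabolites), name="metabolite").to_csv(
            out / "key_metabolites.tsv", sep="\t", index=False
        )
        report.stages["associate"] = {
            "design_unit": design.unit,
            "n_observations": len(design.X),
            "n_zero_variance_groups": len(design.zero_variance),
            "n_selected_groups": len(keys.selected_groups),
            "n_key_metabolites": len(keys.key_metabolites),
            "threshold": config.key_threshold,
        }
        if len(keys.selected_groups) >= 1 and keys.coefficients.shape[1] >= 2:
            try:
                clustering = cluster_variables(
                    keys.coefficients, n_clusters=config.n_variable_clusters
                )
                pd.Series(clustering.flat_clusters, name="cluster").to_csv(
                    out / "variable_clusters.tsv", sep="\t", index_label="variable"
                )
                report.stages["associate"]["n_variable_clusters"] = len(
                    set(clustering.flat_clusters.values())
                )
            except ValueError as exc:  # all-zero profiles possible on null data
                report.warnings.append({"stage": "associate", "message": str(exc)})
    except Exception as exc:
        raise RuntimeError(f"stage 'associate' failed: {exc}") from exc

    try:
        stage("mincom")
        mincom_cond = _load_library(config)[config.mincom_condition]
        mincom_dir = out / "mincom"
        mincom_dir.mkdir(exist_ok=True)
        per_site: dict[str, dict] = {}
        for system in systems:
            if system.scale != "genome_resolved":
                continue
            if not keys.key_metabolites:
                report.warnings.append(
                    {"stage": "mincom", "message": "no key metabolites selected"}
                )
                break
            tset = filter_targets(system, mincom_cond, keys.key_metabolites)
            if not tset.producible:
                per_site[system.site] = {
                    "n_targets_producible": 0,
                    "n_targets_unproducible": len(tset.unproducible),
                }
                continue
            sols = enumerate_solutions(
                system, mincom_cond, tset.producible, cap=config.solution_cap
            )
            sols.write_json(mincom_dir / f"{system.site}.json")
            entry = {
                "n_targets_producible": len(tset.producible),
                "n_targets_unproducible": len(tset.unproducible),
                "k": sols.k,
                "n_solutions": sols.n_solutions,
                "n_key_species": len(sols.key_species),
                "n_essential": len(sols.essential),
                "n_alternative": len(sols.alternative),
                "mc_ks_percent": sols.mc_ks_percent,
                "capped": sols.capped,
            }
            if not sols.capped:
                subs = substitutable_groups(sols)
                (mincom_dir / f"{system.site}_substitutable.json").write_text(
                    subs.to_json()
                )
                entry["n_substitutable_classes"] = len(subs.classes)
            per_site[system.site] = entry
        report.stages["mincom"] = per_site
    except Exception as exc:
        raise RuntimeError(f"stage 'mincom' failed: {exc}") from exc

    (out / "report.json").write_text(report.to_json() + "\n")
    logger.info("run complete in %.1fs", time.time() - t0)
    return report
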