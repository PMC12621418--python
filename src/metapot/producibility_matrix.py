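"""The simulation grid and the binary producibility matrix.

Every (system, condition) pair is one simulation; its scope becomes one binary
column (1 = producible). The study design is 6 sites x 2 scales x 5 conditions
= 60 columns. Downstream steps: remove gap-fill artifacts (metabolites ever
producible at genome_resolved scale but never at metagenome scale, attributed
to reconstruction gap-filling), collapse metabolites with identical
producibility vectors into *metabolite groups*, and extract *core metabolites*
(producible in every site x condition combination of a scale).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .community_scope import SystemSpec, community_scope
from .conditions import SeedCondition

logger = logging.getLogger("metapot")

__all__ = [
    "ProducibilityMatrix",
    "MetaboliteGroup",
    "run_grid",
    "filter_gapfill_artifacts",
    "collapse_groups",
    "core_metabolites",
]


@dataclass
class ProducibilityMatrix:
    """Binary metabolites x simulations matrix with per-column metadata.

    ``data`` is indexed by metabolite id; columns are simulation ids
    ``site|scale|condition``. ``meta`` is indexed by simulation id with
    columns site/scale/condition. ``seed_convention`` records whether seed
    compounds were excluded from scopes ("exclusive") or kept ("inclusive").
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    seed_convention: str = "exclusive"

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[0]

    @property
    def n_simulations(self) -> int:
        return self.data.shape[1]

    def scales(self) -> set[str]:
        return set(self.meta["scale"])

    def columns_for_scale(self, scale: str) -> list[str]:
        return list(self.meta.index[self.meta["scale"] == scale])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="metabolite")

    def save(self, directory: str | Path) -> None:
        """Write matrix.tsv + columns.tsv (+ convention marker) to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_tsv(directory / "matrix.tsv")
        self.meta.to_csv(directory / "columns.tsv", sep="\t", index_label="simulation")
        (directory / "matrix_meta.json").write_text(
            json.dumps({"seed_convention": self.seed_convention}) + "\n"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ProducibilityMatrix":
        directory = Path(directory)
        data = pd.read_csv(directory / "matrix.tsv", sep="\t", index_col="metabolite")
        data.index.name = None
        meta = pd.read_csv(directory / "columns.tsv", sep="\t", index_col="simulation")
        meta.index.name = None
        convention = "exclusive"
        marker = directory / "matrix_meta.json"
        if marker.exists():
            convention = json.loads(marker.read_text())["seed_convention"]
        return cls(data.astype(np.int8), meta, convention)

    def to_triplets(self) -> dict:
        rows, cols = np.nonzero(self.data.to_numpy())
        return {
            "metabolites": list(self.data.index),
            "simulations": list(self.data.columns),
            "entries": [[int(r), int(c)] for r, c in zip(rows, cols)],
            "seed_convention": self.seed_convention,
        }


def run_grid(
    systems: list[SystemSpec],
    conditions: list[SeedCondition],
    *,
    include_seeds: bool = False,
) -> ProducibilityMatrix:
    """Run every (system, condition) simulation and assemble the matrix.

    Columns are ordered by the given system and condition order; rows are the
    sorted union of all scopes, so permuting the system list changes only
    column order. Duplicate grid cells are an error, and every cell must
    produce a scope (zeros are meaningful; nothing is imputed).
    """
    cells: list[tuple[str, dict]] = []
    seen: set[tuple[str, str, str]] = set()
    scopes: dict[str, frozenset[str]] = {}
    for system in systems:
        for condition in conditions:
            key = (system.site, system.scale, condition.name)
            if key in seen:
                raise ValueError(f"duplicate grid cell {key}")
            seen.add(key)
            sim_id = f"{system.site}|{system.scale}|{condition.name}"
            scope = community_scope(system, condition, include_seeds=include_seeds)
            scopes[sim_id] = scope
            cells.append(
                (
                    sim_id,
                    {
                        "site": system.site,
                        "scale": system.scale,
                        "condition": condition.name,
                    },
                )
            )
            logger.info("grid cell %s: scope size %d", sim_id, len(scope))

    universe = sorted(set().union(*scopes.values())) if scopes else []
    sim_ids = [sim_id for sim_id, _ in cells]
    data = pd.DataFrame(0, index=universe, columns=sim_ids, dtype=np.int8)
    for sim_id, scope in scopes.items():
        data.loc[sorted(scope), sim_id] = 1
    meta = pd.DataFrame([m for _, m in cells], index=sim_ids)
    return ProducibilityMatrix(
        data=data,
        meta=meta,
        seed_convention="inclusive" if include_seeds else "exclusive",
    )


def filter_gapfill_artifacts(
    matrix: ProducibilityMatrix,
) -> tuple[ProducibilityMatrix, list[str]]:
    """Drop metabolites producible at genome_resolved scale but never at
    metagenome scale.

    Genome-resolved reconstructions may contain gap-filled reactions absent
    from the community-wide network; compounds reachable only through them are
    artifacts of reconstruction, not community metabolism. Idempotent. With a
    single scale present the matrix is returned unchanged with a warning.
    """
    scales = matrix.scales()
    if {"metagenome", "genome_resolved"} - scales:
        warnings.warn(
            "gap-fill artifact filter needs both scales; matrix has "
            f"{sorted(scales)} — returning unchanged",
            stacklevel=2,
        )
        return matrix, []
    mag_cols = matrix.columns_for_scale("genome_resolved")
    metag_cols = matrix.columns_for_scale("metagenome")
    in_mag = matrix.data[mag_cols].any(axis=1)
    in_metag = matrix.data[metag_cols].any(axis=1)
    removed = list(matrix.data.index[in_mag & ~in_metag])
    kept = matrix.data.drop(index=removed)
    logger.info("gap-fill artifact filter removed %d metabolites", len(removed))
    return (
        ProducibilityMatrix(kept, matrix.meta.copy(), matrix.seed_convention),
        removed,
    )


@dataclass(frozen=True)
class MetaboliteGroup:
    """Maximal set of metabolites sharing one producibility vector."""

    id: str
    members: tuple[str, ...]
    vector: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.members)


def collapse_groups(matrix: ProducibilityMatrix) -> list[MetaboliteGroup]:
    """Partition matrix rows into groups of identical binary vectors.

    Group ids are ``g0001``... assigned after sorting groups by (vector as a
    bit-string, lexicographically first member), so naming is stable across
    runs and row orders.
    """
    buckets: dict[tuple[int, ...], list[str]] = {}
    arr = matrix.data.to_numpy()
    for mid, row in zip(matrix.data.index, arr):
        buckets.setdefault(tuple(int(v) for v in row), []).append(mid)
    ordered = sorted(
        buckets.items(), key=lambda kv: ("".join(map(str, kv[0])), min(kv[1]))
    )
    return [
        MetaboliteGroup(f"g{i:04d}", tuple(sorted(members)), vector)
        for i, (vector, members) in enumerate(ordered, start=1)
    ]


def groups_to_frame(
    groups: list[MetaboliteGroup], matrix: ProducibilityMatrix
) -> pd.DataFrame:
    """Group-level matrix: one row per group, same columns as ``matrix``."""
    data = pd.DataFrame(
        [g.vector for g in groups],
        index=[g.id for g in groups],
        columns=matrix.data.columns,
        dtype=np.int8,
    )
    return data


def groups_table(groups: list[MetaboliteGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [g.id for g in groups],
            "size": [len(g) for g in groups],
            "members": [",".join(g.members) for g in groups],
            "vector": ["".join(map(str, g.vector)) for g in groups],
        }
    ).set_index("group")


def core_metabolites(matrix: ProducibilityMatrix, scale: str) -> frozenset[str]:
    """Metabolites producible in every simulation column of one scale."""
    if scale not in {"metagenome", "genome_resolved"}:
        raise ValueError(f"unknown scale {scale!r}")
    cols = matrix.columns_for_scale(scale)
    if not cols:
        return frozenset()
    mask = matrix.data[cols].all(axis=1)
    return frozenset(matrix.data.index[mask])
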