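"""Orchestration of the six core builds and the consolidated collection.

Six strategies pair a data source with an optimization criterion:
GenAN/GenEN (Modified Rogers distance on SNPs), PhenAN/PhenEN (Gower on
consensus phenotypes), GPmAN/GPmEN (the blended phenotype+genotype
distance), each at the same sampling intensity (default 10%). The
consolidated collection keeps every accession selected by at least
``min_votes`` (default 2) of the strategies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_formats import PipelineError, SelectionMatrix
from .distance_engine import DistanceMatrix
from .core_selector import (
    CoreSolution,
    ObjectiveSpec,
    OptimizerConfig,
    core_size,
    optimize_core,
)

__all__ = ["BuildPlan", "build_all", "consolidate", "overlap_summary"]

DEFAULT_METHODS = (
    ("GenAN", "modified_rogers", "AN"),
    ("GenEN", "modified_rogers", "EN"),
    ("PhenAN", "gower", "AN"),
    ("PhenEN", "gower", "EN"),
    ("GPmAN", "blended", "AN"),
    ("GPmEN", "blended", "EN"),
)


@dataclass(frozen=True)
class BuildPlan:
    """The six strategy descriptors: (name, distance kind, objective)."""

    methods: tuple[tuple[str, str, str], ...] = DEFAULT_METHODS
    fraction: float = 0.10
    seeds: tuple[int, ...] | None = None  # one per method
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self) -> None:
        names = [m[0] for m in self.methods]
        if len(set(names)) != len(names):
            raise PipelineError("duplicate method name in build plan")
        if self.seeds is not None and len(self.seeds) != len(self.methods):
            raise PipelineError("need one seed per method")
        if not (0 < self.fraction <= 1):
            raise PipelineError("fraction must be in (0, 1]")


def build_all(
    plan: BuildPlan, distances: dict[str, DistanceMatrix]
) -> SelectionMatrix:
    """Run every strategy in the plan and collect binary memberships."""
    registries = {d.accession_ids for d in distances.values()}
    if len(registries) > 1:
        raise PipelineError("distance matrices have mismatched accession registries")
    for name, kind, _ in plan.methods:
        if kind not in distances:
            raise PipelineError(f"method {name!r} needs missing distance {kind!r}")
    ids = next(iter(distances.values())).accession_ids
    n = len(ids)
    size = core_size(n, plan.fraction)
    seeds = plan.seeds or tuple(range(len(plan.methods)))
    columns, solutions = [], {}
    for (name, kind, objective), seed in zip(plan.methods, seeds):
        cfg = OptimizerConfig(
            n_replicas=plan.optimizer.n_replicas,
            t_min=plan.optimizer.t_min,
            t_max=plan.optimizer.t_max,
            steps=plan.optimizer.steps,
            exchange_interval=plan.optimizer.exchange_interval,
            stall_limit=plan.optimizer.stall_limit,
            seed=seed,
        )
        sol = optimize_core(distances[kind], size, ObjectiveSpec(objective), cfg)
        columns.append(sol.membership(n))
        solutions[name] = sol
    sel = SelectionMatrix(
        accession_ids=ids,
        method_names=tuple(m[0] for m in plan.methods),
        membership=np.column_stack(columns),
        metadata={
            "core_size": size,
            "fraction": plan.fraction,
            "seeds": dict(zip((m[0] for m in plan.methods), seeds)),
            "objective_values": {
                k: s.objective_value for k, s in solutions.items()
            },
        },
    )
    return sel


def consolidate(sel: SelectionMatrix, min_votes: int = 2) -> np.ndarray:
    """Membership vector of accessions selected by >= ``min_votes`` methods."""
    if min_votes < 1:
        raise PipelineError("min_votes must be >= 1")
    if len(sel.method_names) < 2:
        raise PipelineError("consolidation needs >=2 method columns")
    votes = sel.membership.sum(axis=1)
    member = (votes >= min_votes).astype(np.int8)
    # pigeonhole: the consolidated set can never exceed total picks / votes
    assert member.sum() <= sel.membership.sum() / min_votes + 1e-9
    if member.sum() == 0:
        warnings.warn("consolidated collection is empty (collections disjoint)")
    return member


def with_consolidated(sel: SelectionMatrix, min_votes: int = 2) -> SelectionMatrix:
    return SelectionMatrix(
        accession_ids=sel.accession_ids,
        method_names=sel.method_names,
        membership=sel.membership,
        consolidated=consolidate(sel, min_votes),
        metadata={**sel.metadata, "min_votes": min_votes},
    )


def overlap_summary(sel: SelectionMatrix) -> dict:
    """UpSet-style overlap accounting across method columns.

    Returns exclusive counts per method (selected by that method only), the
    never-selected count, and the full intersection table keyed by method
    combination (counts of accessions selected by exactly that combination).
    """
    if len(sel.method_names) < 1:
        raise PipelineError("need >=1 method column")
    m = sel.membership.astype(bool)
    names = sel.method_names
    totals = m.sum(axis=1)
    exclusive = {
        name: int((m[:, j] & (totals == 1)).sum()) for j, name in enumerate(names)
    }
    never = int((totals == 0).sum())
    patterns: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(range(len(names)), k):
            mask = np.ones(len(sel.accession_ids), dtype=bool)
            for j in range(len(names)):
                mask &= m[:, j] if j in combo else ~m[:, j]
            cnt = int(mask.sum())
            if cnt:
                patterns[tuple(names[j] for j in combo)] = cnt
    return {
        "exclusive": exclusive,
        "never_selected": never,
        "intersections": patterns,
    }


def overlap_table(sel: SelectionMatrix) -> pd.DataFrame:
    s = overlap_summary(sel)
    rows = [
        {"methods": "+".join(combo), "degree": len(combo), "count": cnt}
        for combo, cnt in sorted(
            s["intersections"].items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    rows.append({"methods": "(none)", "degree": 0, "count": s["never_selected"]})
    return pd.DataFrame(rows)
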