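"""Fixed-size core-subset selection by stochastic parallel tempering.

Two objectives drive selection, both defined on a precomputed accession
distance matrix:

* **AN** (accession-to-nearest-entry): mean over *all* accessions of the
  distance to the nearest core entry (entries contribute 0). Minimized —
  small AN means every accession is well represented by the core.
* **EN** (entry-to-nearest-entry): mean over core entries of the distance to
  the nearest *other* entry. Maximized — large EN means the core is spread
  out and non-redundant.

The optimizer runs several Metropolis chains at different temperatures over
fixed-size subsets, with a single swap (one selected accession for one
unselected) as the move, and periodically proposes state exchanges between
neighboring temperatures. Deterministic for a fixed seed. Greedy and random
baselines are provided for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import PipelineError
from .distance_engine import DistanceMatrix

__all__ = [
    "ObjectiveSpec",
    "OptimizerConfig",
    "CoreSolution",
    "core_size",
    "objective_AN",
    "objective_EN",
    "optimize_core",
    "greedy_core",
    "random_core",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """AN is minimized; EN is maximized. Direction follows from the kind."""

    kind: str  # "AN" | "EN"
    include_entries: bool = True  # AN averages over entries too (at 0)

    def __post_init__(self) -> None:
        if self.kind not in ("AN", "EN"):
            raise PipelineError(f"unknown objective {self.kind!r}")

    @property
    def direction(self) -> str:
        return "minimize" if self.kind == "AN" else "maximize"


@dataclass(frozen=True)
class OptimizerConfig:
    """Parallel-tempering budget; all knobs are deliberate configuration."""

    n_replicas: int = 4
    t_min: float = 1e-4
    t_max: float = 1e-1
    steps: int = 50_000  # Metropolis steps per replica
    exchange_interval: int = 100
    stall_limit: int = 10_000  # stop when best-ever unimproved this long
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max):
            raise PipelineError("need 0 < t_min < t_max")
        for k in ("n_replicas", "steps", "exchange_interval", "stall_limit"):
            if getattr(self, k) < 1:
                raise PipelineError(f"{k} must be positive")

    @property
    def ladder(self) -> np.ndarray:
        return np.geomspace(self.t_min, self.t_max, self.n_replicas)


@dataclass
class CoreSolution:
    selected: np.ndarray  # sorted indices into the accession registry
    objective_value: float
    objective: ObjectiveSpec
    trace: np.ndarray  # best-ever value at each recorded step
    config: OptimizerConfig | None = None
    seed: int | None = None
    accession_ids: tuple[str, ...] = ()

    @property
    def selected_ids(self) -> tuple[str, ...]:
        return tuple(self.accession_ids[i] for i in self.selected)

    def membership(self, n: int) -> np.ndarray:
        v = np.zeros(n, dtype=np.int8)
        v[self.selected] = 1
        return v


def core_size(n_total: int, fraction: float) -> int:
    """Core size = ceil(fraction * N), clamped to [2, N].

    The clamp keeps the EN objective defined (a 1-entry core has no nearest
    other entry).
    """
    if n_total < 1:
        raise PipelineError("n_total must be >= 1")
    if not (0 < fraction <= 1):
        raise PipelineError("fraction must be in (0, 1]")
    return min(max(math.ceil(fraction * n_total), 2), n_total)


def objective_AN(
    d: DistanceMatrix | np.ndarray, subset, *, include_entries: bool = True
) -> float:
    """Mean accession-to-nearest-entry distance (entries contribute 0)."""
    v = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    idx = np.asarray(list(subset), dtype=int)
    if idx.size == 0:
        raise PipelineError("AN objective needs a non-empty subset")
    nearest = v[:, idx].min(axis=1)
    if include_entries:
        return float(nearest.mean())
    mask = np.ones(v.shape[0], dtype=bool)
    mask[idx] = False
    if not mask.any():
        return 0.0
    return float(nearest[mask].mean())


def objective_EN(d: DistanceMatrix | np.ndarray, subset) -> float:
    """Mean entry-to-nearest-other-entry distance within the core."""
    v = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    idx = np.asarray(list(subset), dtype=int)
    if idx.size < 2:
        raise PipelineError("EN objective needs >=2 entries")
    sub = v[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _evaluate(v: np.ndarray, idx: np.ndarray, obj: ObjectiveSpec) -> float:
    if obj.kind == "AN":
        return objective_AN(v, idx, include_entries=obj.include_entries)
    return objective_EN(v, idx)


def optimize_core(
    d: DistanceMatrix,
    size: int,
    obj: ObjectiveSpec,
    cfg: OptimizerConfig | None = None,
) -> CoreSolution:
    """Parallel-tempering search over fixed-size subsets.

    Energy is the objective for AN (minimize) and its negative for EN, so
    every chain minimizes energy; swaps between neighboring temperatures use
    the standard two-replica acceptance. The best subset ever visited by any
    replica is returned; it is never worse than the initial state.
    """
    cfg = cfg or OptimizerConfig()
    v = d.values
    n = v.shape[0]
    if size < 2 or size > n:
        raise PipelineError(f"core size {size} out of range [2, {n}]")
    rng = np.random.default_rng(cfg.seed)
    sign = 1.0 if obj.direction == "minimize" else -1.0
    temps = cfg.ladder
    r = cfg.n_replicas

    subsets, in_core, energies = [], [], []
    for _ in range(r):
        sel = rng.choice(n, size=size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[sel] = True
        subsets.append(sel)
        in_core.append(mask)
        energies.append(sign * _evaluate(v, sel, obj))
    best_idx = int(np.argmin(energies))
    best_energy = energies[best_idx]
    best_subset = subsets[best_idx].copy()
    trace = [sign * best_energy]
    stall = 0

    if size == n:  # whole collection: nothing to search
        sel = np.arange(n)
        return CoreSolution(
            selected=sel,
            objective_value=_evaluate(v, sel, obj),
            objective=obj,
            trace=np.asarray([_evaluate(v, sel, obj)]),
            config=cfg,
            seed=cfg.seed,
            accession_ids=d.accession_ids,
        )

    n_sweeps = cfg.steps
    for step in range(n_sweeps):
        for k in range(r):
            sel, mask = subsets[k], in_core[k]
            out_pos = rng.integers(size)
            leave = sel[out_pos]
            enter = rng.integers(n)
            while mask[enter]:
                enter = rng.integers(n)
            cand = sel.copy()
            cand[out_pos] = enter
            e_new = sign * _evaluate(v, cand, obj)
            delta = e_new - energies[k]
            if delta <= 0 or rng.random() < math.exp(-delta / temps[k]):
                mask[leave] = False
                mask[enter] = True
                subsets[k] = cand
                energies[k] = e_new
                if e_new < best_energy - 1e-15:
                    best_energy = e_new
                    best_subset = cand.copy()
                    stall = 0
        stall += 1
        if (step + 1) % cfg.exchange_interval == 0:
            trace.append(sign * best_energy)
            for k in range(r - 1):
                a = (1.0 / temps[k] - 1.0 / temps[k + 1]) * (
                    energies[k] - energies[k + 1]
                )
                if a >= 0 or rng.random() < math.exp(a):
                    subsets[k], subsets[k + 1] = subsets[k + 1], subsets[k]
                    in_core[k], in_core[k + 1] = in_core[k + 1], in_core[k]
                    energies[k], energies[k + 1] = energies[k + 1], energies[k]
        if stall >= cfg.stall_limit:
            break

    best_subset = np.sort(best_subset)
    value = _evaluate(v, best_subset, obj)
    trace.append(value)
    return CoreSolution(
        selected=best_subset,
        objective_value=value,
        objective=obj,
        trace=np.asarray(trace),
        config=cfg,
        seed=cfg.seed,
        accession_ids=d.accession_ids,
    )


def greedy_core(d: DistanceMatrix, size: int, obj: ObjectiveSpec) -> CoreSolution:
    """Deterministic greedy baseline.

    EN starts from the pair attaining the maximum distance and adds the
    accession with the best marginal objective each step; AN starts from the
    medoid (minimum summed distance) and adds greedily.
    """
    v = d.values
    n = v.shape[0]
    if not (2 <= size <= n):
        raise PipelineError(f"core size {size} out of range [2, {n}]")
    if obj.kind == "EN":
        i, j = np.unravel_index(np.argmax(v), v.shape)
        sel = [int(i), int(j)]
    else:
        medoid = int(np.argmin(v.sum(axis=0)))
        second = int(np.argsort(v.sum(axis=0))[1])
        sel = [medoid, second]
    chosen = set(sel)
    while len(sel) < size:
        best_c, best_val = None, None
        for c in range(n):
            if c in chosen:
                continue
            val = _evaluate(v, np.asarray(sel + [c]), obj)
            better = (
                best_val is None
                or (obj.direction == "minimize" and val < best_val)
                or (obj.direction == "maximize" and val > best_val)
            )
            if better:
                best_c, best_val = c, val
        sel.append(best_c)
        chosen.add(best_c)
    sel_arr = np.sort(np.asarray(sel))
    value = _evaluate(v, sel_arr, obj)
    return CoreSolution(
        selected=sel_arr,
        objective_value=value,
        objective=obj,
        trace=np.asarray([value]),
        accession_ids=d.accession_ids,
    )


def random_core(d: DistanceMatrix, size: int, seed: int,
                obj: ObjectiveSpec | None = None) -> CoreSolution:
    """Uniform random subset baseline (seeded)."""
    v = d.values
    n = v.shape[0]
    if not (2 <= size <= n):
        raise PipelineError(f"core size {size} out of range [2, {n}]")
    obj = obj or ObjectiveSpec("EN")
    rng = np.random.default_rng(seed)
    sel = np.sort(rng.choice(n, size=size, replace=False))
    value = _evaluate(v, sel, obj)
    return CoreSolution(
        selected=sel,
        objective_value=value,
        objective=obj,
        trace=np.asarray([value]),
        seed=seed,
        accession_ids=d.accession_ids,
    )
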