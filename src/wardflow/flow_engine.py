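"""The dynamic loop: per arrival-rate step, rebuild adjusted residuals, find
augmenting paths by depth-first search over positive-residual edges, push
forward-only flow, and maintain the run-long records.

Backward residual edges are deliberately never created: patients do not take
alternative care pathways, so augmentation only depletes forward residuals.
Two records persist across steps: ``DynamicResidualGraph`` (per-edge min/max
residual over the run) and the per-ward residual time series (``DynV``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .capacity_adjust import (
    StaticResidualGraph,
    build_static_residual,
    compute_vertex_loads,
)
from .network_model import ArrivalProfile, HospitalNetwork
from .service_time import ServiceTimeDistribution, sample_step_time

#: Residuals above this count as "positive" for path finding; a strict zero
#: threshold would admit phantom paths from floating-point dust.
POSITIVE_EPS = 1e-12


@dataclass(frozen=True)
class RunConfig:
    """Knobs for one simulation run; defaults reproduce the reference loop."""

    samples_per_step: int = 1
    vertex_arrival: str = "raw"          # "raw" | "weighted"
    max_augmentations_per_step: int | None = None
    arrival_capped: bool = False          # cap augmentations at ceil(r_t)
    keep_path_log: bool = True
    carry_over_residuals: bool = False    # experiment: deplete across steps

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AugmentingPath:
    wards: tuple[str, ...]
    bottleneck: float

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.wards[:-1], self.wards[1:]))


@dataclass
class DynamicResidualGraph:
    """Running per-edge min/max residual capacity over the whole run."""

    min_cap: dict[tuple[str, str], float]
    max_cap: dict[tuple[str, str], float]
    _sum: dict[tuple[str, str], float] = field(default_factory=dict)
    _count: int = 0

    @classmethod
    def empty(cls, edges: Iterable[tuple[str, str]]) -> "DynamicResidualGraph":
        edges = list(edges)
        return cls(
            {e: math.inf for e in edges},
            {e: -math.inf for e in edges},
            {e: 0.0 for e in edges},
        )

    def observe(self, residuals: Mapping[tuple[str, str], float]) -> None:
        for e, value in residuals.items():
            if value < self.min_cap[e]:
                self.min_cap[e] = value
            if value > self.max_cap[e]:
                self.max_cap[e] = value
            self._sum[e] += value
        self._count += 1

    def mean_cap(self) -> dict[tuple[str, str], float]:
        if self._count == 0:
            return {e: math.nan for e in self._sum}
        return {e: s / self._count for e, s in self._sum.items()}

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(self.min_cap)


@dataclass
class StepResult:
    step: int
    arrival_rate: float
    s_times: dict[str, float]
    paths: list[AugmentingPath]
    residuals: StaticResidualGraph

    @property
    def total_flow(self) -> float:
        return sum(p.bottleneck for p in self.paths)


@dataclass
class SimulationResult:
    """Everything a run produces: the dynamic records, the path log, and
    enough configuration echo to reproduce it bit-for-bit."""

    net: HospitalNetwork
    dynrg: DynamicResidualGraph
    dynv: dict[str, list[float]]
    path_log: list[tuple[int, AugmentingPath]]
    config: RunConfig
    seed: int | None
    steps: int
    total_flow: float

    def dynv_array(self, ward: str) -> np.ndarray:
        return np.asarray(self.dynv[ward], dtype=float)


# ---------------------------------------------------------------------------
# Path search and augmentation


def _adjacency(net: HospitalNetwork) -> dict[str, list[tuple[str, str]]]:
    """Out-edges per ward ordered by descending distribution probability,
    ties broken by input order (stable sort)."""
    order: dict[str, list] = {w.name: [] for w in net.wards}
    for e in net.pathways:
        order[e.source].append(e)
    return {
        name: [(e.source, e.target) for e in sorted(edges, key=lambda e: -e.probability)]
        for name, edges in order.items()
    }


def dfs_find_path(
    residuals: StaticResidualGraph,
    source: str,
    sink: str,
    adjacency: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> AugmentingPath | None:
    """Depth-first search for a source-to-sink path through strictly
    positive residuals; returns ``None`` when the sink is unreachable.

    Simple paths only (a visited set bars revisiting a ward), so the search
    terminates on cyclic networks.  Neighbor order follows ``adjacency``
    when given, else insertion order of the residual map.
    """
    if adjacency is None:
        adjacency = {}
        for (u, v) in residuals.residuals:
            adjacency.setdefault(u, []).append((u, v))
    elif source not in adjacency:
        # a network adjacency knows every ward; absence means a bad name
        # (edge-derived adjacency can't tell "no out-edges" from "unknown")
        raise KeyError(f"unknown source {source!r}")

    stack: list[tuple[str, list]] = [(source, list(adjacency.get(source, ())))]
    on_path: list[str] = [source]
    visited = {source}
    while stack:
        node, edges = stack[-1]
        advanced = False
        while edges:
            u, v = edges.pop(0)
            if v in visited:
                continue
            if residuals.residuals.get((u, v), 0.0) <= POSITIVE_EPS:
                continue
            visited.add(v)
            on_path.append(v)
            if v == sink:
                path = tuple(on_path)
                bottleneck = min(residuals.residuals[e] for e in zip(path[:-1], path[1:]))
                return AugmentingPath(path, bottleneck)
            stack.append((v, list(adjacency.get(v, ()))))
            advanced = True
            break
        if not advanced:
            stack.pop()
            on_path.pop()
    return None


def path_bottleneck(residuals: StaticResidualGraph, path: AugmentingPath) -> float:
    if len(path.wards) < 2:
        raise ValueError("path must contain at least one edge")
    return min(residuals.residuals[e] for e in path.edges)


def augment(residuals: StaticResidualGraph, path: AugmentingPath, amount: float) -> None:
    """Push ``amount`` of flow forward along the path, in place.

    Every on-path residual drops by exactly ``amount``; no backward residual
    edges are created or incremented.
    """
    if amount <= 0:
        raise ValueError("augmentation amount must be > 0")
    bottleneck = path_bottleneck(residuals, path)
    if amount > bottleneck + 1e-12:
        raise ValueError(f"amount {amount} exceeds path bottleneck {bottleneck}")
    for e in path.edges:
        residuals.residuals[e] -= amount


# ---------------------------------------------------------------------------
# The per-step loop


def run_time_step(
    net: HospitalNetwork,
    residuals: StaticResidualGraph,
    arrival_rate: float,
    s_times: Mapping[str, float],
    config: RunConfig = RunConfig(),
    adjacency: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> StepResult:
    """Push flow until no positive source-to-sink path remains (or the
    configured augmentation cap is hit); the residual graph is depleted in
    place and returned inside the :class:`StepResult`."""
    if adjacency is None:
        adjacency = _adjacency(net)
    cap = config.max_augmentations_per_step
    if config.arrival_capped:
        arrival_cap = max(0, math.ceil(arrival_rate))
        cap = arrival_cap if cap is None else min(cap, arrival_cap)
    paths: list[AugmentingPath] = []
    while cap is None or len(paths) < cap:
        path = dfs_find_path(residuals, net.source_name, net.sink_name, adjacency)
        if path is None:
            break
        augment(residuals, path, path.bottleneck)
        paths.append(path)
    return StepResult(
        step=residuals.step,
        arrival_rate=arrival_rate,
        s_times=dict(s_times),
        paths=paths,
        residuals=residuals,
    )


def _ward_residual(
    net: HospitalNetwork, residuals: StaticResidualGraph, ward: str
) -> float:
    """Per-ward DynV value: mean of post-augmentation residuals over the
    ward's incoming edges (the source, having none, uses its outgoing)."""
    edges = net.out_edges(ward) if ward == net.source_name else net.in_edges(ward)
    if not edges:
        return math.nan
    values = [residuals.residuals[(e.source, e.target)] for e in edges]
    return float(np.mean(values))


def run_simulation(
    net: HospitalNetwork,
    arrivals: ArrivalProfile,
    distributions: Mapping[str, ServiceTimeDistribution],
    config: RunConfig = RunConfig(),
    seed: int | None = 0,
) -> SimulationResult:
    """Run the full dynamic loop over the arrival profile.

    Per step: sample one service time per interior ward, rebuild the static
    residual graph from the adjustment formulas, push flow until blocked,
    then fold the post-augmentation residuals into the run-long records.
    Deterministic given identical inputs and seed.
    """
    missing = [w.name for w in net.interior_wards if w.name not in distributions]
    if missing:
        raise ValueError(f"no service-time distribution for wards: {missing}")
    rng = np.random.default_rng(seed)
    adjacency = _adjacency(net)
    dynrg = DynamicResidualGraph.empty(
        (e.source, e.target) for e in net.pathways
    )
    dynv: dict[str, list[float]] = {w.name: [] for w in net.wards}
    path_log: list[tuple[int, AugmentingPath]] = []
    total_flow = 0.0
    carried: StaticResidualGraph | None = None

    for t, r_t in enumerate(arrivals.rates):
        s_times = {
            w.name: sample_step_time(distributions[w.name], rng, config.samples_per_step)
            for w in net.interior_wards
        }
        loads = compute_vertex_loads(net, r_t, s_times, config.vertex_arrival)
        residuals = build_static_residual(net, r_t, loads, step=t)
        if config.carry_over_residuals and carried is not None:
            # experiment: keep each residual no higher than what the previous
            # step left behind, so depletion persists across steps
            for e, prev in carried.residuals.items():
                residuals.residuals[e] = min(residuals.residuals[e], prev)
        step = run_time_step(net, residuals, r_t, s_times, config, adjacency)
        total_flow += step.total_flow
        if config.keep_path_log:
            path_log.extend((t, p) for p in step.paths)
        dynrg.observe(residuals.residuals)
        for w in net.wards:
            dynv[w.name].append(_ward_residual(net, residuals, w.name))
        carried = residuals

    return SimulationResult(
        net=net,
        dynrg=dynrg,
        dynv=dynv,
        path_log=path_log,
        config=config,
        seed=seed,
        steps=arrivals.t_max,
        total_flow=total_flow,
    )


# ---------------------------------------------------------------------------
# Result serialization (plain-text tables)


def write_result(result: SimulationResult, outdir) -> None:
    """Write dynrg.csv, edge_means.csv, dynv.csv, paths.jsonl, manifest.json."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "min_cap": result.dynrg.min_cap[(u, v)],
                "max_cap": result.dynrg.max_cap[(u, v)],
            }
            for (u, v) in result.dynrg.edges
        ]
    ).to_csv(outdir / "dynrg.csv", index=False)
    pd.DataFrame(
        [
            {"source": u, "target": v, "mean_cap": m}
            for (u, v), m in result.dynrg.mean_cap().items()
        ]
    ).to_csv(outdir / "edge_means.csv", index=False)
    pd.DataFrame(
        [
            {"ward": w, "step": t, "residual": value}
            for w, series in result.dynv.items()
            for t, value in enumerate(series)
        ]
    ).to_csv(outdir / "dynv.csv", index=False)
    with open(outdir / "paths.jsonl", "w") as fh:
        for t, p in result.path_log:
            fh.write(
                json.dumps({"step": t, "wards": list(p.wards), "bottleneck": p.bottleneck})
                + "\n"
            )
    manifest = {
        "seed": result.seed,
        "steps": result.steps,
        "total_flow": result.total_flow,
        "config": result.config.to_dict(),
        "source": result.net.source_name,
        "sink": result.net.sink_name,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
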