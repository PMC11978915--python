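"""Bottleneck diagnostics derived from a simulation result.

Three edge matrices summarise the run-long residual record: persistency
(max − min, fluctuation of an edge's behaviour), severity (0 − max, how far
the edge stays at or over capacity even in its best state) and overflow
(0 − min, how hard it overflowed at worst).  Blockage coloring marks wards
and edges never visited by any augmenting path.  Root-cause traces walk the
network k hops up or down from a focal ward.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow_engine import DynamicResidualGraph, SimulationResult
from .network_model import HospitalNetwork

MATRIX_LABELS = ("persistency", "severity", "overflow")


@dataclass(frozen=True)
class EdgeMatrix:
    """A real value per network edge; cells exist only where an edge does."""

    label: str
    values: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": u, "target": v, "value": x}
                for (u, v), x in self.values.items()
            ],
            columns=["source", "target", "value"],
        )

    def to_dense(self, ward_order) -> pd.DataFrame:
        """Ward-by-ward pivot with NaN where no edge exists (heatmap input)."""
        ward_order = list(ward_order)
        frame = pd.DataFrame(np.nan, index=ward_order, columns=ward_order)
        for (u, v), x in self.values.items():
            frame.loc[u, v] = x
        return frame


def _check_observed(dynrg: DynamicResidualGraph) -> None:
    unobserved = [e for e, m in dynrg.min_cap.items() if math.isinf(m)]
    if unobserved:
        raise ValueError(f"edges never observed: {unobserved}")


def persistency_matrix(dynrg: DynamicResidualGraph) -> EdgeMatrix:
    """max − min residual per edge; small values mean stable behaviour."""
    _check_observed(dynrg)
    return EdgeMatrix(
        "persistency",
        {e: dynrg.max_cap[e] - dynrg.min_cap[e] for e in dynrg.edges},
    )


def severity_matrix(dynrg: DynamicResidualGraph) -> EdgeMatrix:
    """0 − max residual; ≥ 0 means at/over capacity even at its best."""
    _check_observed(dynrg)
    return EdgeMatrix("severity", {e: 0.0 - dynrg.max_cap[e] for e in dynrg.edges})


def overflow_matrix(dynrg: DynamicResidualGraph) -> EdgeMatrix:
    """0 − min residual; positive means the edge overflowed at least once."""
    _check_observed(dynrg)
    return EdgeMatrix("overflow", {e: 0.0 - dynrg.min_cap[e] for e in dynrg.edges})


@dataclass(frozen=True)
class BlockageColoring:
    ward_status: dict[str, str]      # reached | blocked | source | sink
    edge_status: dict[tuple[str, str], str]
    reached_count: int               # over non-source/sink wards
    blocked_count: int


def blockage_classification(
    result: SimulationResult, net: HospitalNetwork | None = None
) -> BlockageColoring:
    """Color wards/edges by whether any augmenting path ever visited them.

    Requires the path log; a ward absent from every path over the whole run
    is "blocked" (its count excludes the source and sink, which carry their
    own status)."""
    if net is None:
        net = result.net
    if not result.config.keep_path_log:
        raise ValueError("blockage classification requires the path log")
    reached_wards: set[str] = set()
    reached_edges: set[tuple[str, str]] = set()
    for _t, path in result.path_log:
        reached_wards.update(path.wards)
        reached_edges.update(path.edges)

    ward_status = {}
    for w in net.wards:
        if w.name == net.source_name:
            ward_status[w.name] = "source"
        elif w.name == net.sink_name:
            ward_status[w.name] = "sink"
        else:
            ward_status[w.name] = "reached" if w.name in reached_wards else "blocked"
    edge_status = {
        (e.source, e.target): "reached" if (e.source, e.target) in reached_edges else "blocked"
        for e in net.pathways
    }
    interior = [s for s in ward_status.values() if s in ("reached", "blocked")]
    return BlockageColoring(
        ward_status,
        edge_status,
        reached_count=interior.count("reached"),
        blocked_count=interior.count("blocked"),
    )


@dataclass(frozen=True)
class FilteredSeries:
    ward: str
    values: tuple[float, ...]
    dropped: int


def ward_timeseries(
    dynv: dict[str, list[float]],
    wards,
    outlier_bound: float = 1000.0,
) -> dict[str, FilteredSeries]:
    """Per-ward residual series with values outside ±``outlier_bound``
    dropped; NaNs (wards with no incoming edges) are dropped too."""
    out: dict[str, FilteredSeries] = {}
    for name in wards:
        if name not in dynv:
            raise KeyError(f"unknown ward {name!r}")
        series = dynv[name]
        kept = tuple(
            v for v in series if not math.isnan(v) and -outlier_bound <= v <= outlier_bound
        )
        out[name] = FilteredSeries(name, kept, len(series) - len(kept))
    return out


@dataclass(frozen=True)
class TraceEntry:
    ward: str
    depth: int
    score: float


@dataclass(frozen=True)
class RootCauseTrace:
    focal: str
    direction: str               # predecessors | successors
    depth: int
    entries: tuple[TraceEntry, ...]   # ranked, ties broken by name


def _k_hop(net: HospitalNetwork, start: str, k: int, backwards: bool) -> dict[str, int]:
    """BFS depth of every ward within k hops (excluding the start)."""
    depths = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if depths[node] >= k:
            continue
        edges = net.in_edges(node) if backwards else net.out_edges(node)
        for e in edges:
            nxt = e.source if backwards else e.target
            if nxt not in depths:
                depths[nxt] = depths[node] + 1
                queue.append(nxt)
    depths.pop(start)
    return depths


def trace_root_cause(
    result: SimulationResult,
    ward: str,
    depth: int,
    net: HospitalNetwork | None = None,
) -> tuple[RootCauseTrace, RootCauseTrace]:
    """Trace suspected bottleneck causes up to ``depth`` hops around a ward.

    Predecessors are ranked by total flow pushed along logged paths that
    pass through them before reaching the focal ward (high inflow pressure);
    successors by their mean outgoing residual over the run (low residual =
    suspected blocker).  Returns (predecessor trace, successor trace).
    """
    if net is None:
        net = result.net
    if ward not in net.ward_names:
        raise KeyError(f"unknown ward {ward!r}")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    pred_depths = _k_hop(net, ward, depth, backwards=True)
    pushed = {name: 0.0 for name in pred_depths}
    for _t, path in result.path_log:
        if ward not in path.wards:
            continue
        focal_at = path.wards.index(ward)
        for upstream in path.wards[:focal_at]:
            if upstream in pushed:
                pushed[upstream] += path.bottleneck
    pred_entries = sorted(
        (TraceEntry(name, d, pushed[name]) for name, d in pred_depths.items()),
        key=lambda e: (-e.score, e.ward),
    )

    succ_depths = _k_hop(net, ward, depth, backwards=False)
    edge_mean = result.dynrg.mean_cap()
    succ_entries = []
    for name, d in succ_depths.items():
        outs = [(e.source, e.target) for e in net.out_edges(name)]
        score = float(np.mean([edge_mean[e] for e in outs])) if outs else math.inf
        succ_entries.append(TraceEntry(name, d, score))
    succ_entries.sort(key=lambda e: (e.score, e.ward))  # low residual first

    return (
        RootCauseTrace(ward, "predecessors", depth, tuple(pred_entries)),
        RootCauseTrace(ward, "successors", depth, tuple(succ_entries)),
    )


# ---------------------------------------------------------------------------
# Report writing


def write_report(
    result: SimulationResult,
    outdir,
    focal_ward: str | None = None,
    depth: int = 3,
    outlier_bound: float = 1000.0,
    top_k: int = 3,
    heatmaps: bool = False,
) -> None:
    """Emit persistency/severity/overflow CSVs, blockage GraphML, filtered
    time series and an optional root-cause JSON into ``outdir``."""
    import json
    from pathlib import Path

    from .network_model import export_graph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrices = {
        "persistency": persistency_matrix(result.dynrg),
        "severity": severity_matrix(result.dynrg),
        "overflow": overflow_matrix(result.dynrg),
    }
    for label, matrix in matrices.items():
        matrix.to_frame().to_csv(outdir / f"{label}.csv", index=False)

    coloring = blockage_classification(result)
    export_graph(
        result.net,
        outdir / "blockage.graphml",
        vertex_annotations={w: {"status": s} for w, s in coloring.ward_status.items()},
        edge_annotations={e: {"status": s} for e, s in coloring.edge_status.items()},
    )

    filtered = ward_timeseries(result.dynv, result.dynv.keys(), outlier_bound)
    pd.DataFrame(
        [
            {"ward": f.ward, "index": i, "residual": v}
            for f in filtered.values()
            for i, v in enumerate(f.values)
        ],
        columns=["ward", "index", "residual"],
    ).to_csv(outdir / "timeseries.csv", index=False)

    if focal_ward is not None:
        preds, succs = trace_root_cause(result, focal_ward, depth)
        payload = {
            "focal": focal_ward,
            "depth": depth,
            "predecessors": [
                {"ward": e.ward, "depth": e.depth, "pushed_flow": e.score}
                for e in preds.entries[:top_k]
            ],
            "successors": [
                {"ward": e.ward, "depth": e.depth, "mean_outgoing_residual": e.score}
                for e in succs.entries[:top_k]
            ],
        }
        with open(outdir / "root_cause.json", "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    if heatmaps:
        _render_heatmaps(result, matrices, outdir)


def _render_heatmaps(result, matrices, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.net.ward_names
    for label, matrix in matrices.items():
        fig, ax = plt.subplots(figsize=(8, 7))
        dense = matrix.to_dense(order)
        im = ax.imshow(dense.values, cmap="viridis")
        ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
        ax.set_yticks(range(len(order)), order, fontsize=6)
        ax.set_title(label)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(outdir / f"{label}.png", dpi=120)
        plt.close(fig)
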