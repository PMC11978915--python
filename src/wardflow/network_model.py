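"""Hospital network construction, validation, transformation and serialization.

The hospital is a directed graph: wards are vertices carrying a bed capacity
and a server (staff) count, care pathways are edges carrying a waiting-queue
capacity and a distribution probability.  Exactly one source and one sink
mark where patients enter and leave; they are ordinary :class:`Ward` records
with sentinel capacities so they never constrain flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

#: Bed/server count given to source and sink so they never bind.
SENTINEL_CAPACITY = 10**9

#: Outgoing distribution probabilities must sum to 1 within this tolerance.
PROB_SUM_TOL = 1e-6


class NetworkError(ValueError):
    """Raised when input tables violate the network contract."""


@dataclass(frozen=True)
class Ward:
    """A hospital unit: ``beds`` physical capacity, ``servers`` staff count.

    ``los_values`` holds observed lengths of stay in hours; it may be empty
    for the source and sink, which only mark flow entry and exit.
    """

    name: str
    beds: int
    servers: int
    los_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.beds, int) or self.beds < 1:
            raise NetworkError(f"ward {self.name!r}: beds must be a positive integer")
        if not isinstance(self.servers, int) or self.servers < 1:
            raise NetworkError(f"ward {self.name!r}: servers must be a positive integer")
        if any(v <= 0 for v in self.los_values):
            raise NetworkError(f"ward {self.name!r}: all LOS values must be > 0")
        object.__setattr__(self, "los_values", tuple(float(v) for v in self.los_values))


@dataclass(frozen=True)
class CarePathway:
    """A directed transfer route with a waiting-queue capacity and the
    fraction of the upstream ward's patients that take it."""

    source: str
    target: str
    queue_capacity: float
    probability: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise NetworkError(f"self-loop on ward {self.source!r}")
        if self.queue_capacity < 0:
            raise NetworkError(f"edge {self.source}->{self.target}: queue capacity < 0")
        if not 0.0 <= self.probability <= 1.0:
            raise NetworkError(
                f"edge {self.source}->{self.target}: probability {self.probability} outside [0, 1]"
            )


@dataclass(frozen=True)
class ArrivalProfile:
    """Ordered arrival rates (patients/hour), one per time step."""

    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rates) < 1:
            raise NetworkError("arrival profile must contain at least one rate")
        if any(r < 0 for r in self.rates):
            raise NetworkError("arrival rates must be >= 0")
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))

    @property
    def t_max(self) -> int:
        return len(self.rates)

    def repeat(self, times: int) -> "ArrivalProfile":
        """Tile the profile, e.g. a 24-hour day repeated over a week."""
        if times < 1:
            raise NetworkError("repeat count must be >= 1")
        return ArrivalProfile(self.rates * times)


@dataclass
class ValidationReport:
    issues: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)

    def add(self, severity: str, ident: str, message: str) -> None:
        self.issues.append((severity, ident, message))

    def errors(self) -> list[tuple[str, str, str]]:
        return [i for i in self.issues if i[0] == "error"]


@dataclass(frozen=True)
class HospitalNetwork:
    """Immutable ward graph with a designated source and sink.

    Edge order follows the input table; DFS tie-breaking and serialization
    rely on it being stable.
    """

    wards: tuple[Ward, ...]
    pathways: tuple[CarePathway, ...]
    source_name: str
    sink_name: str

    @property
    def n(self) -> int:
        return len(self.wards)

    @property
    def m(self) -> int:
        return len(self.pathways)

    def ward(self, name: str) -> Ward:
        try:
            return self._ward_index[name]
        except KeyError:
            raise KeyError(f"unknown ward {name!r}") from None

    @property
    def _ward_index(self) -> dict[str, Ward]:
        # cached lazily on the instance; frozen dataclass so go via __dict__
        idx = self.__dict__.get("_ward_index_cache")
        if idx is None:
            idx = {w.name: w for w in self.wards}
            self.__dict__["_ward_index_cache"] = idx
        return idx

    @property
    def ward_names(self) -> tuple[str, ...]:
        return tuple(w.name for w in self.wards)

    @property
    def interior_wards(self) -> tuple[Ward, ...]:
        """All wards except the source and sink."""
        return tuple(
            w for w in self.wards if w.name not in (self.source_name, self.sink_name)
        )

    def out_edges(self, name: str) -> tuple[CarePathway, ...]:
        return tuple(e for e in self.pathways if e.source == name)

    def in_edges(self, name: str) -> tuple[CarePathway, ...]:
        return tuple(e for e in self.pathways if e.target == name)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for w in self.wards:
            g.add_node(w.name, beds=w.beds, servers=w.servers)
        for e in self.pathways:
            g.add_edge(
                e.source, e.target, capacity=e.queue_capacity, probability=e.probability
            )
        return g


def _check_structure(net: HospitalNetwork, report: ValidationReport) -> None:
    names = [w.name for w in net.wards]
    seen: set[str] = set()
    for name in names:
        if name in seen:
            report.add("error", name, "duplicate ward name")
        seen.add(name)
    for endpoint in (net.source_name, net.sink_name):
        if endpoint not in seen:
            report.add("error", endpoint, "designated source/sink is not a ward")
    if net.source_name == net.sink_name:
        report.add("error", net.source_name, "source and sink must differ")

    pair_seen: set[tuple[str, str]] = set()
    for e in net.pathways:
        for endpoint in (e.source, e.target):
            if endpoint not in seen:
                report.add(
                    "error", f"{e.source}->{e.target}", f"edge endpoint {endpoint!r} is not a ward"
                )
        if (e.source, e.target) in pair_seen:
            report.add("error", f"{e.source}->{e.target}", "parallel edge")
        pair_seen.add((e.source, e.target))


def validate_network(net: HospitalNetwork) -> ValidationReport:
    """Check every network invariant; violations are reported, never thrown.

    Errors: duplicate/dangling names, parallel edges, probability sums
    outside tolerance, source with inbound edges, sink with outbound edges,
    sink unreachable.  Cycles only warn — patients may legitimately return
    to earlier wards.
    """
    report = ValidationReport()
    _check_structure(net, report)
    if report.errors():
        return report

    for w in net.wards:
        outgoing = net.out_edges(w.name)
        if outgoing and w.name != net.sink_name:
            total = sum(e.probability for e in outgoing)
            if abs(total - 1.0) > PROB_SUM_TOL:
                report.add(
                    "error",
                    w.name,
                    f"outgoing distribution probabilities sum to {total!r}, expected 1",
                )

    if net.in_edges(net.source_name):
        report.add("error", net.source_name, "source in-degree must be 0")
    if net.out_edges(net.sink_name):
        report.add("error", net.sink_name, "sink out-degree must be 0")

    g = net.to_networkx()
    if net.source_name in g and net.sink_name in g:
        if not nx.has_path(g, net.source_name, net.sink_name):
            report.add("error", net.sink_name, "sink not reachable from source")
        unreachable = [
            w.name for w in net.interior_wards if not nx.has_path(g, net.source_name, w.name)
        ]
        for name in unreachable:
            report.add("warning", name, "ward not reachable from source")
    if g.number_of_nodes() and not nx.is_directed_acyclic_graph(g):
        report.add("warning", "network", "network contains cycles")
    return report


def build_network(
    wards: Iterable[Ward],
    pathways: Iterable[CarePathway],
    source_name: str,
    sink_name: str,
    *,
    validate: bool = True,
) -> HospitalNetwork:
    net = HospitalNetwork(tuple(wards), tuple(pathways), source_name, sink_name)
    if validate:
        report = validate_network(net)
        if not report.ok:
            msgs = "; ".join(f"{ident}: {msg}" for _, ident, msg in report.errors())
            raise NetworkError(f"invalid network: {msgs}")
    return net


# ---------------------------------------------------------------------------
# Tabular I/O


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path, **kwargs)
    sep = "\t" if suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep, **kwargs)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise NetworkError(f"{what} table missing columns: {missing}")


def load_network(
    wards_table: str | Path,
    edges_table: str | Path,
    source_name: str,
    sink_name: str,
    los_table: str | Path | None = None,
) -> HospitalNetwork:
    """Load a hospital network from adjacency-list tables.

    ``wards_table`` needs columns ``ward,beds,staff`` (blank staff falls back
    to beds), ``edges_table`` needs ``source,target,capacity,probability``,
    and the optional ``los_table`` needs ``ward,los_hours`` with one row per
    observed stay.  Ward names are whitespace-trimmed and case-sensitive.
    Raises :class:`NetworkError` on any invariant violation.
    """
    wards_df = _read_table(wards_table)
    _require_columns(wards_df, ("ward", "beds", "staff"), "wards")
    edges_df = _read_table(edges_table)
    _require_columns(edges_df, ("source", "target", "capacity", "probability"), "edges")

    los_map: dict[str, list[float]] = {}
    if los_table is not None:
        los_df = _read_table(los_table)
        _require_columns(los_df, ("ward", "los_hours"), "LOS")
        for _, row in los_df.iterrows():
            los_map.setdefault(str(row["ward"]).strip(), []).append(float(row["los_hours"]))

    wards = []
    for _, row in wards_df.iterrows():
        name = str(row["ward"]).strip()
        try:
            beds = int(row["beds"])
            staff = row["staff"]
            servers = beds if pd.isna(staff) else int(staff)
        except (TypeError, ValueError) as exc:
            raise NetworkError(f"ward {name!r}: non-numeric beds/staff field") from exc
        if name in (source_name, sink_name):
            # entry/exit markers never constrain flow
            beds = servers = SENTINEL_CAPACITY
        wards.append(Ward(name, beds, servers, tuple(los_map.get(name, ()))))

    pathways = []
    for _, row in edges_df.iterrows():
        try:
            pathways.append(
                CarePathway(
                    str(row["source"]).strip(),
                    str(row["target"]).strip(),
                    float(row["capacity"]),
                    float(row["probability"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise NetworkError(f"edge row {row.to_dict()!r}: non-numeric field") from exc

    return build_network(wards, pathways, source_name, sink_name)


def load_arrivals(path: str | Path) -> ArrivalProfile:
    """Load an arrival-rate series from ``hour,rate`` or a one-column list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"arrival profile not found: {path}")
    df = _read_table(path)
    if "rate" in df.columns:
        if "hour" in df.columns:
            df = df.sort_values("hour")
        rates = df["rate"].astype(float).tolist()
    elif df.shape[1] == 1:
        col = df.columns[0]
        rates = df[col].astype(float).tolist()
        # headerless single column: the header cell is itself a rate
        try:
            rates.insert(0, float(col))
        except ValueError:
            pass
    else:
        raise NetworkError("arrival profile needs a 'rate' column or a single column")
    return ArrivalProfile(tuple(rates))


def set_equal_distribution(net: HospitalNetwork) -> HospitalNetwork:
    """Replace every distribution probability with 1/outdegree of its ward."""
    outdeg: dict[str, int] = {}
    for e in net.pathways:
        outdeg[e.source] = outdeg.get(e.source, 0) + 1
    new_edges = tuple(
        replace(e, probability=1.0 / outdeg[e.source]) for e in net.pathways
    )
    return HospitalNetwork(net.wards, new_edges, net.source_name, net.sink_name)


# ---------------------------------------------------------------------------
# Graph export


def export_graph(
    net: HospitalNetwork,
    path: str | Path,
    vertex_annotations: Mapping[str, Mapping[str, object]] | None = None,
    edge_annotations: Mapping[tuple[str, str], Mapping[str, object]] | None = None,
) -> Path:
    """Write the network to GraphML (default) or DOT, chosen by extension.

    Annotations are extra attributes keyed by ward name or (source, target)
    pair; unknown keys raise ``KeyError``.
    """
    path = Path(path)
    g = net.to_networkx()
    g.graph["source"] = net.source_name
    g.graph["sink"] = net.sink_name
    if vertex_annotations:
        for name, attrs in vertex_annotations.items():
            if name not in g:
                raise KeyError(f"annotation for unknown ward {name!r}")
            g.nodes[name].update(attrs)
    if edge_annotations:
        for (u, v), attrs in edge_annotations.items():
            if not g.has_edge(u, v):
                raise KeyError(f"annotation for unknown edge {u!r}->{v!r}")
            g.edges[u, v].update(attrs)
    if path.suffix.lower() in (".dot", ".gv"):
        _write_dot(g, path)
    else:
        nx.write_graphml(g, path)
    return path


def _dot_quote(s: object) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    lines = ["digraph hospital {"]
    for node, attrs in g.nodes(data=True):
        attr_s = ", ".join(f"{k}={_dot_quote(v)}" for k, v in attrs.items())
        lines.append(f"  {_dot_quote(node)} [{attr_s}];")
    for u, v, attrs in g.edges(data=True):
        attr_s = ", ".join(f"{k}={_dot_quote(val)}" for k, val in attrs.items())
        lines.append(f"  {_dot_quote(u)} -> {_dot_quote(v)} [{attr_s}];")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def import_graphml(path: str | Path) -> HospitalNetwork:
    """Rebuild a :class:`HospitalNetwork` from a GraphML file written by
    :func:`export_graph`.  LOS values are not round-tripped."""
    g = nx.read_graphml(path)
    source = g.graph.get("source")
    sink = g.graph.get("sink")
    if source is None or sink is None:
        raise NetworkError("GraphML file lacks source/sink graph attributes")
    wards = tuple(
        Ward(str(n), int(d["beds"]), int(d["servers"])) for n, d in g.nodes(data=True)
    )
    edges = tuple(
        CarePathway(str(u), str(v), float(d["capacity"]), float(d["probability"]))
        for u, v, d in g.edges(data=True)
    )
    return build_network(wards, edges, str(source), str(sink))


def write_network_tables(
    net: HospitalNetwork, wards_path: str | Path, edges_path: str | Path,
    los_path: str | Path | None = None,
) -> None:
    """Serialize the network back to the adjacency-list CSV schema."""
    pd.DataFrame(
        [
            {"ward": w.name, "beds": w.beds, "staff": w.servers}
            for w in net.wards
        ]
    ).to_csv(wards_path, index=False)
    pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "capacity": e.queue_capacity,
                "probability": e.probability,
            }
            for e in net.pathways
        ]
    ).to_csv(edges_path, index=False)
    if los_path is not None:
        rows = [
            {"ward": w.name, "los_hours": v}
            for w in net.wards
            for v in w.los_values
        ]
        pd.DataFrame(rows, columns=["ward", "los_hours"]).to_csv(los_path, index=False)


def is_finite_number(x: object) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)
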