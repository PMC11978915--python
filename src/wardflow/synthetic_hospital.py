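"""Synthetic hospital networks, arrival profiles and service-time fixtures.

``make_toy_hospital`` returns a fixed, versioned 20-ward / 62-edge network
(committed as data in :data:`TOY_WARDS` / :data:`TOY_EDGES`, never
regenerated) that honours the structural constraints every other module
assumes: one source, one sink, all queue capacities 5, outgoing
probabilities summing to 1, probabilities weighted by ward importance.
``make_random_hospital`` generalizes it for property tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network_model import (
    ArrivalProfile,
    CarePathway,
    HospitalNetwork,
    NetworkError,
    SENTINEL_CAPACITY,
    Ward,
    build_network,
    validate_network,
)
from .service_time import ServiceTimeDistribution, constant_distribution

SOURCE = "Source"
SINK = "Sink"

#: name -> (beds, base LOS in hours).  Source/sink get sentinel capacities.
TOY_WARDS: dict[str, tuple[int, float]] = {
    SOURCE: (0, 0.0),
    SINK: (0, 0.0),
    "Emergency Department": (36, 6.0),
    "Infectious diseases Unit": (24, 96.0),
    "Medical Ward": (32, 72.0),
    "Cardiac": (26, 60.0),
    "Respiratory": (24, 54.0),
    "Surgical Ward": (28, 48.0),
    "Orthopedics": (22, 80.0),
    "Intensive Care Unit": (24, 120.0),
    "Pediatrics": (24, 36.0),
    "Maternity": (22, 48.0),
    "Oncology": (26, 110.0),
    "Neurology": (23, 90.0),
    "Geriatrics": (28, 160.0),
    "Psychiatry": (21, 200.0),
    "Radiology": (21, 3.0),
    "Laboratory": (21, 2.0),
    "Recovery": (25, 24.0),
    "Urology": (22, 50.0),
}

#: (source, target, probability) — queue capacity is 5 on every edge.
#: Probabilities reflect ward importance (the Emergency Department takes
#: most arrivals) and sum to 1 per ward.
TOY_EDGES: tuple[tuple[str, str, float], ...] = (
    (SOURCE, "Emergency Department", 0.70),
    (SOURCE, "Infectious diseases Unit", 0.10),
    (SOURCE, "Medical Ward", 0.10),
    (SOURCE, "Maternity", 0.10),
    ("Emergency Department", "Intensive Care Unit", 0.15),
    ("Emergency Department", "Surgical Ward", 0.15),
    ("Emergency Department", "Medical Ward", 0.20),
    ("Emergency Department", "Cardiac", 0.10),
    ("Emergency Department", "Respiratory", 0.10),
    ("Emergency Department", "Orthopedics", 0.10),
    ("Emergency Department", "Pediatrics", 0.05),
    ("Emergency Department", "Psychiatry", 0.05),
    ("Emergency Department", SINK, 0.10),
    ("Infectious diseases Unit", "Medical Ward", 0.30),
    ("Infectious diseases Unit", "Intensive Care Unit", 0.20),
    ("Infectious diseases Unit", SINK, 0.50),
    ("Medical Ward", "Cardiac", 0.15),
    ("Medical Ward", "Respiratory", 0.15),
    ("Medical Ward", "Geriatrics", 0.20),
    ("Medical Ward", "Urology", 0.10),
    ("Medical Ward", "Recovery", 0.20),
    ("Medical Ward", SINK, 0.20),
    ("Cardiac", "Intensive Care Unit", 0.20),
    ("Cardiac", "Recovery", 0.30),
    ("Cardiac", "Radiology", 0.10),
    ("Cardiac", SINK, 0.40),
    ("Respiratory", "Intensive Care Unit", 0.15),
    ("Respiratory", "Recovery", 0.35),
    ("Respiratory", SINK, 0.50),
    ("Surgical Ward", "Recovery", 0.40),
    ("Surgical Ward", "Intensive Care Unit", 0.20),
    ("Surgical Ward", "Orthopedics", 0.10),
    ("Surgical Ward", SINK, 0.30),
    ("Orthopedics", "Recovery", 0.30),
    ("Orthopedics", "Radiology", 0.10),
    ("Orthopedics", SINK, 0.60),
    ("Intensive Care Unit", "Medical Ward", 0.30),
    ("Intensive Care Unit", "Neurology", 0.30),
    ("Intensive Care Unit", SINK, 0.40),
    ("Pediatrics", "Infectious diseases Unit", 0.20),
    ("Pediatrics", "Laboratory", 0.10),
    ("Pediatrics", SINK, 0.70),
    ("Maternity", "Pediatrics", 0.20),
    ("Maternity", SINK, 0.80),
    ("Oncology", "Recovery", 0.30),
    ("Oncology", SINK, 0.70),
    ("Neurology", "Recovery", 0.30),
    ("Neurology", "Geriatrics", 0.20),
    ("Neurology", SINK, 0.50),
    ("Geriatrics", "Recovery", 0.20),
    ("Geriatrics", SINK, 0.80),
    ("Psychiatry", "Laboratory", 0.10),
    ("Psychiatry", SINK, 0.90),
    ("Radiology", "Oncology", 0.30),
    ("Radiology", "Surgical Ward", 0.20),
    ("Radiology", SINK, 0.50),
    ("Laboratory", "Infectious diseases Unit", 0.30),
    ("Laboratory", SINK, 0.70),
    ("Recovery", "Medical Ward", 0.10),
    ("Recovery", SINK, 0.90),
    ("Urology", "Recovery", 0.20),
    ("Urology", SINK, 0.80),
)

TOY_QUEUE_CAPACITY = 5.0

SPIKE_ARRIVALS = (
    1, 1, 1, 1, 1, 1, 1, 10, 20, 30, 40, 30, 20, 10,
    1, 1, 1, 1, 1, 1, 1, 1, 1, 1,
)


def make_toy_hospital(seed: int | None = None, servers_rule: str = "equal-to-beds") -> HospitalNetwork:
    """The fixed small-hospital fixture: 20 wards, 62 care pathways.

    ``seed`` only affects the synthetic LOS lists (5 deterministic values
    around each ward's base stay); the topology is a committed constant.
    ``servers_rule`` is ``equal-to-beds`` (default), ``half-beds`` or
    ``double-beds`` — the staffing scenarios used in behaviour experiments.
    """
    rng = np.random.default_rng(0 if seed is None else seed)
    wards = []
    for name, (beds, base_los) in TOY_WARDS.items():
        if name in (SOURCE, SINK):
            wards.append(Ward(name, SENTINEL_CAPACITY, SENTINEL_CAPACITY))
            continue
        servers = _apply_servers_rule(beds, servers_rule)
        spread = rng.uniform(0.6, 1.4, size=5)
        los = tuple(sorted(float(base_los * s) for s in spread))
        wards.append(Ward(name, beds, servers, los))
    edges = tuple(
        CarePathway(u, v, TOY_QUEUE_CAPACITY, p) for u, v, p in TOY_EDGES
    )
    return build_network(wards, edges, SOURCE, SINK)


def make_spike_arrivals() -> ArrivalProfile:
    """The 24-hour arrival profile with a mid-day surge peaking at 40/h."""
    return ArrivalProfile(tuple(float(r) for r in SPIKE_ARRIVALS))


def _apply_servers_rule(beds: int, rule: str) -> int:
    if rule == "equal-to-beds":
        return beds
    if rule == "half-beds":
        return max(1, math.ceil(beds / 2))
    if rule == "double-beds":
        return beds * 2
    raise ValueError(f"unknown servers rule {rule!r}")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters for :func:`make_random_hospital`."""

    n_wards: int = 10                 # total vertices, incl. source and sink
    edge_density: float = 0.3         # extra-edge probability beyond the spine
    beds_range: tuple[int, int] = (5, 30)
    servers_rule: str = "equal-to-beds"
    explicit_servers: int | None = None
    queue_capacity: float = 5.0
    los_range: tuple[float, float] = (2.0, 200.0)
    los_count: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wards < 3:
            raise NetworkError("need at least source, sink and one ward")
        if not 0.0 <= self.edge_density <= 1.0:
            raise NetworkError("edge_density must be in [0, 1]")


def make_random_hospital(params: GeneratorParams) -> HospitalNetwork:
    """Generate a random valid hospital network, deterministic per seed.

    Interior wards are ordered in layers; a spine guarantees every ward is
    reachable from the source and reaches the sink, extra forward edges are
    added per ``edge_density``, then probabilities are normalized per ward.
    """
    rng = np.random.default_rng(params.seed)
    n_interior = params.n_wards - 2
    names = [f"Ward {i:02d}" for i in range(n_interior)]

    wards = [Ward(SOURCE, SENTINEL_CAPACITY, SENTINEL_CAPACITY)]
    lo_beds, hi_beds = params.beds_range
    for name in names:
        beds = int(rng.integers(lo_beds, hi_beds + 1))
        if params.servers_rule == "explicit":
            if params.explicit_servers is None:
                raise NetworkError("explicit servers rule needs explicit_servers")
            servers = params.explicit_servers
        else:
            servers = _apply_servers_rule(beds, params.servers_rule)
        los = tuple(
            sorted(
                float(v)
                for v in rng.uniform(params.los_range[0], params.los_range[1], params.los_count)
            )
        )
        wards.append(Ward(name, beds, servers, los))
    wards.append(Ward(SINK, SENTINEL_CAPACITY, SENTINEL_CAPACITY))

    # spine: source -> ward 0 -> ... -> last ward -> sink, all forward,
    # so connectivity holds by construction
    edge_set: set[tuple[str, str]] = set()
    ordered = [SOURCE, *names, SINK]
    for a, b in zip(ordered[:-1], ordered[1:]):
        edge_set.add((a, b))
    for i, a in enumerate(ordered[:-1]):
        if a == SOURCE:
            candidates = names
        else:
            candidates = ordered[i + 2 :]  # strictly forward: acyclic
        for b in candidates:
            if b == a or (a, b) in edge_set:
                continue
            if rng.random() < params.edge_density:
                edge_set.add((a, b))

    # per-ward probabilities ~ Dirichlet (normalized uniforms)
    by_source: dict[str, list[str]] = {}
    for a, b in sorted(edge_set):
        by_source.setdefault(a, []).append(b)
    edges = []
    for a, targets in by_source.items():
        weights = rng.uniform(0.1, 1.0, len(targets))
        weights = weights / weights.sum()
        for b, p in zip(targets, weights):
            edges.append(CarePathway(a, b, params.queue_capacity, float(p)))

    net = build_network(wards, edges, SOURCE, SINK, validate=False)
    report = validate_network(net)
    if not report.ok:
        raise NetworkError(f"generated network invalid: {report.errors()}")
    return net


def make_constant_service(
    net: HospitalNetwork, value: float
) -> dict[str, ServiceTimeDistribution]:
    """Constant service-time distribution at ``value`` hours for every
    interior ward (the benchmark scenario uses 5.01)."""
    if value <= 0:
        raise ValueError("service time must be > 0")
    return {w.name: constant_distribution(value) for w in net.interior_wards}


def fitted_toy_distributions(
    net: HospitalNetwork, family: str = "lognormal"
) -> dict[str, ServiceTimeDistribution]:
    """Fit per-ward distributions from the toy fixture's LOS lists."""
    from .service_time import fit_distribution

    return {
        w.name: fit_distribution(w.los_values, family) for w in net.interior_wards
    }
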