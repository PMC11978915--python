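"""Per-step capacity adjustment: service rates, flow intensities, overflow
ratios, edge inflows, and the static residual graph they produce.

A ward's intensity compares the arrival rate against what its servers can
process; intensity 0 means idle, 1 exactly full, above 1 overflowed.  The
adjusted capacities are real-valued and may go negative — a negative
residual measures how hard an edge or ward is overflowed, not a patient
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .network_model import HospitalNetwork

#: |1 - intensity| below this counts as "exactly full" (adjusted capacity 0).
EPSILON_FULL = 1e-9

#: Sentinel returned by overflow_ratio at intensity exactly 1.
FULL_SENTINEL = math.inf


def service_rate(servers: int, s_time: float) -> float:
    """Patients/hour a ward can process: servers over the sampled service time."""
    if servers < 1:
        raise ValueError("servers must be >= 1")
    if s_time <= 0:
        raise ValueError("service time must be > 0")
    return servers / s_time


def flow_intensity(arrival_rate: float, srv_rate: float) -> float:
    """Arrival rate over service rate (dimensionless utilisation)."""
    if srv_rate <= 0:
        raise ValueError("service rate must be > 0")
    if arrival_rate < 0:
        raise ValueError("arrival rate must be >= 0")
    return arrival_rate / srv_rate


def overflow_ratio(intensity: float) -> float:
    """Current intensity over remaining intensity, rho / (1 - rho).

    At rho == 1 (within :data:`EPSILON_FULL`) returns :data:`FULL_SENTINEL`;
    :func:`adjust_vertex_capacity` consumes that as adjusted capacity 0.
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if abs(1.0 - intensity) < EPSILON_FULL:
        return FULL_SENTINEL
    return intensity / (1.0 - intensity)


def adjust_vertex_capacity(beds: int, intensity: float) -> float:
    """Beds-equivalent capacity left after accounting for utilisation.

    Positive iff rho < 1, zero at rho == 1, negative iff rho > 1, and
    non-increasing in rho; never exceeds the physical bed count.
    """
    if beds < 1:
        raise ValueError("beds must be >= 1")
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if intensity == 0:
        return float(beds)
    ratio = overflow_ratio(intensity)
    if math.isinf(ratio):
        return 0.0
    return min(float(beds), beds / ratio)


def edge_inflow(arrival_rate: float, probability: float) -> float:
    """Patients/hour arriving at an edge: arrival rate times its share."""
    if arrival_rate < 0:
        raise ValueError("arrival rate must be >= 0")
    if not 0 <= probability <= 1:
        raise ValueError("probability must be in [0, 1]")
    return arrival_rate * probability


def adjust_edge_capacity(queue_capacity: float, inflow: float) -> float:
    """Queue slots left after the step's inflow; negative when overloaded."""
    if queue_capacity < 0:
        raise ValueError("queue capacity must be >= 0")
    if inflow < 0:
        raise ValueError("inflow must be >= 0")
    return queue_capacity - inflow


@dataclass(frozen=True)
class VertexLoad:
    """One ward's adjusted state for a single time step."""

    ward: str
    s_time: float
    service_rate: float
    intensity: float
    overflow_ratio: float
    adjusted_capacity: float


@dataclass(frozen=True)
class EdgeLoad:
    edge: tuple[str, str]
    inflow_rate: float
    adjusted_capacity: float


@dataclass
class StaticResidualGraph:
    """Per-edge adjusted residual capacity for one time step (mutable:
    augmentations deplete it in place)."""

    residuals: dict[tuple[str, str], float]
    step: int = 0

    def copy(self) -> "StaticResidualGraph":
        return StaticResidualGraph(dict(self.residuals), self.step)


def compute_vertex_load(
    ward_name: str,
    beds: int,
    servers: int,
    s_time: float,
    arrival_rate: float,
) -> VertexLoad:
    mu = service_rate(servers, s_time)
    rho = flow_intensity(arrival_rate, mu)
    return VertexLoad(
        ward=ward_name,
        s_time=s_time,
        service_rate=mu,
        intensity=rho,
        overflow_ratio=overflow_ratio(rho) if rho > 0 else 0.0,
        adjusted_capacity=adjust_vertex_capacity(beds, rho),
    )


def compute_vertex_loads(
    net: HospitalNetwork,
    arrival_rate: float,
    s_times: Mapping[str, float],
    vertex_arrival: str = "raw",
) -> dict[str, VertexLoad]:
    """Adjusted load for every interior ward plus the sink.

    ``vertex_arrival='raw'`` applies the hospital arrival rate to every ward;
    ``'weighted'`` scales it by the sum of incoming distribution
    probabilities, attenuating deep wards.
    """
    if vertex_arrival not in ("raw", "weighted"):
        raise ValueError(f"unknown vertex_arrival mode {vertex_arrival!r}")
    loads: dict[str, VertexLoad] = {}
    for w in net.interior_wards:
        rate = arrival_rate
        if vertex_arrival == "weighted":
            rate = arrival_rate * sum(e.probability for e in net.in_edges(w.name))
        loads[w.name] = compute_vertex_load(
            w.name, w.beds, w.servers, s_times[w.name], rate
        )
    return loads


def build_static_residual(
    net: HospitalNetwork,
    arrival_rate: float,
    vertex_loads: Mapping[str, VertexLoad],
    step: int = 0,
) -> StaticResidualGraph:
    """Sum the adjusted edge and target-vertex capacities per edge.

    Edges into the sink carry only the edge term — the sink is a pure exit
    and never constrains flow.
    """
    residuals: dict[tuple[str, str], float] = {}
    for e in net.pathways:
        inflow = edge_inflow(arrival_rate, e.probability)
        value = adjust_edge_capacity(e.queue_capacity, inflow)
        if e.target != net.sink_name:
            try:
                value += vertex_loads[e.target].adjusted_capacity
            except KeyError:
                raise KeyError(f"missing vertex load for ward {e.target!r}") from None
        residuals[(e.source, e.target)] = value
    return StaticResidualGraph(residuals, step)
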