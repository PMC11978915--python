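"""Per-ward service-time distributions with bounded rejection sampling.

Every ward gets a distribution fitted to its observed lengths of stay; every
draw is forced into [min LOS, max LOS] by redrawing (up to a cap, then
clamping), so sampled service times always respect the observed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

FAMILIES = ("lognormal", "truncated-normal", "uniform", "constant")

#: Redraw attempts before the last draw is clamped to the nearest bound.
REJECTION_CAP = 1000


@dataclass(frozen=True)
class ServiceTimeDistribution:
    """A service-time law bounded by the ward's observed LOS range.

    ``params`` is family specific: ``(mu, sigma)`` of log-hours for
    lognormal, ``(mean, sd)`` in hours for truncated-normal, ``()`` for
    uniform, ``(value,)`` for constant.
    """

    family: str
    params: tuple[float, ...]
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not 0 < self.lower_bound <= self.upper_bound:
            raise ValueError(
                f"bounds must satisfy 0 < lower <= upper, got "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )
        if self.family == "constant" and self.lower_bound != self.upper_bound:
            raise ValueError("constant family requires lower_bound == upper_bound")

    @property
    def mean(self) -> float:
        """Closed-form mean of the *unbounded* fitted law (used by tests to
        cross-check sampling; exact only when rejection is rare)."""
        if self.family == "constant":
            return self.params[0]
        if self.family == "uniform":
            return 0.5 * (self.lower_bound + self.upper_bound)
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + 0.5 * sigma**2)
        mean, _sd = self.params
        return mean


def fit_distribution(los_values, family: str = "lognormal") -> ServiceTimeDistribution:
    """Fit a bounded service-time distribution to observed LOS hours.

    Bounds are always min/max of the data.  With a single distinct value any
    family degrades to ``constant`` (a spread cannot be estimated).
    """
    values = np.asarray(list(los_values), dtype=float)
    if values.size == 0:
        raise ValueError("los_values must be non-empty")
    if np.any(values <= 0):
        raise ValueError("all LOS values must be > 0")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    lo, hi = float(values.min()), float(values.max())

    if family == "constant":
        if lo != hi:
            raise ValueError("constant family requires identical LOS values")
        return ServiceTimeDistribution("constant", (lo,), lo, hi)
    if lo == hi:
        # degenerate data: every family collapses to the single value
        return ServiceTimeDistribution("constant", (lo,), lo, hi)
    if family == "uniform":
        return ServiceTimeDistribution("uniform", (), lo, hi)
    if family == "lognormal":
        logs = np.log(values)
        return ServiceTimeDistribution(
            "lognormal", (float(logs.mean()), float(logs.std(ddof=1))), lo, hi
        )
    return ServiceTimeDistribution(
        "truncated-normal", (float(values.mean()), float(values.std(ddof=1))), lo, hi
    )


def constant_distribution(value: float) -> ServiceTimeDistribution:
    if value <= 0:
        raise ValueError("service time must be > 0")
    return ServiceTimeDistribution("constant", (float(value),), float(value), float(value))


def _draw(dist: ServiceTimeDistribution, rng: np.random.Generator) -> float:
    if dist.family == "constant":
        return dist.params[0]
    if dist.family == "uniform":
        return float(rng.uniform(dist.lower_bound, dist.upper_bound))
    if dist.family == "lognormal":
        mu, sigma = dist.params
        return float(rng.lognormal(mu, sigma))
    mean, sd = dist.params
    return float(rng.normal(mean, sd))


def sample_service_time(dist: ServiceTimeDistribution, rng: np.random.Generator) -> float:
    """Draw one service time, rejection-sampled into the LOS bounds.

    Redraws until the value lands in ``[lower_bound, upper_bound]``; after
    :data:`REJECTION_CAP` attempts the last draw is clamped to the nearest
    bound so sampling always terminates.
    """
    value = _draw(dist, rng)
    attempts = 1
    while not dist.lower_bound <= value <= dist.upper_bound:
        if attempts >= REJECTION_CAP:
            return float(min(max(value, dist.lower_bound), dist.upper_bound))
        value = _draw(dist, rng)
        attempts += 1
    return value


def sample_step_time(
    dist: ServiceTimeDistribution, rng: np.random.Generator, samples_per_step: int = 1
) -> float:
    """Service time used for one arrival-rate step: one draw by default,
    or the mean of several when per-patient draws are configured."""
    if samples_per_step < 1:
        raise ValueError("samples_per_step must be >= 1")
    if samples_per_step == 1:
        return sample_service_time(dist, rng)
    return float(
        np.mean([sample_service_time(dist, rng) for _ in range(samples_per_step)])
    )


def fit_all(
    los_by_ward: Mapping[str, object],
    family: str = "lognormal",
    family_overrides: Mapping[str, str] | None = None,
) -> dict[str, ServiceTimeDistribution]:
    """Fit one distribution per ward, honoring per-ward family overrides."""
    overrides = dict(family_overrides or {})
    return {
        name: fit_distribution(values, overrides.get(name, family))
        for name, values in los_by_ward.items()
    }
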