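"""Simulated instrument session: profiling, pressure control, sorting, timing.

The sorter draws sample at a volumetric flow proportional to the applied
sample pressure; with cell concentration ``c`` (cells/mL) the expected event
rate is ``eps = c * flow_per_pressure * pressure``. The controller reads the
observed event rate during each control tick and applies a clamped
multiplicative proportional update toward a target rate — the minimal law
whose fixed point is the target rate. Event *arrival counts* are Poisson;
the event *measurements* are streamed from the sample's stored (shuffled)
order, so the seed governs arrival noise only.

Session time is split into the five categories of the automated workflow —
profiling, sorting, transport, gating, control — with the three
hardware-bound categories taken from configured constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import shapely

from .errors import ValidationError
from .event_io import AxisMapping, EventTable
from .gate_builder import GatePolygon
from .synthetic_cytometry import DEFAULT_CONCENTRATION

#: Default number of cells measured during profiling.
DEFAULT_N_PROFILE = 10_000
#: Default number of cells sorted per sample (one 96-well rescue well).
DEFAULT_N_SORT = 1_200


@dataclass(frozen=True)
class InstrumentModel:
    """Linearised sorter hydraulics and event-rate controller settings.

    Pressure is in arbitrary instrument units; ``flow_per_pressure`` converts
    pressure to sample flow (mL/s per unit). Defaults give the target rate of
    2,000 events/s at mid-range pressure for a 2x10^6 cells/mL sample.
    """

    flow_per_pressure: float = 2.0e-4
    pressure_min: float = 1.0
    pressure_max: float = 10.0
    eps_target: float = 2_000.0
    controller_gain: float = 0.5

    def __post_init__(self) -> None:
        if self.flow_per_pressure <= 0:
            raise ValidationError("flow_per_pressure must be > 0")
        if not self.pressure_min < self.pressure_max:
            raise ValidationError("pressure_min must be below pressure_max")
        if self.eps_target <= 0 or self.controller_gain <= 0:
            raise ValidationError("eps_target and controller_gain must be > 0")


@dataclass(frozen=True)
class SessionTiming:
    """Hardware-bound per-sample durations (seconds), configuration constants."""

    transport: float = 30.0
    gating: float = 5.0
    control: float = 25.0
    control_dt: float = 0.5  # controller tick length during streaming


@dataclass(frozen=True)
class SortPlan:
    n_profile: int = DEFAULT_N_PROFILE
    n_sort: int = DEFAULT_N_SORT
    gate: GatePolygon | None = None

    def __post_init__(self) -> None:
        if self.n_profile <= 0 or self.n_sort <= 0:
            raise ValidationError("n_profile and n_sort must be > 0")


@dataclass
class SortResult:
    sample_id: str
    events_profiled: int
    events_sorted: int
    estimated_concentration: float
    pressure_trace: list[tuple[float, float]]
    phase_times: dict[str, float]
    completed: bool
    shortfall: int = 0
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def total_time(self) -> float:
        return sum(self.phase_times.values())

    def to_dict(self) -> dict[str, Any]:
        return {
            "sample_id": self.sample_id,
            "events_profiled": self.events_profiled,
            "events_sorted": self.events_sorted,
            "estimated_concentration": self.estimated_concentration,
            "phase_times": dict(self.phase_times),
            "total_time": self.total_time,
            "completed": self.completed,
            "shortfall": self.shortfall,
        }


def estimate_concentration(
    eps_observed: float, pressure: float, model: InstrumentModel
) -> float:
    """Cell concentration implied by an observed event rate at a given pressure."""
    if eps_observed < 0:
        raise ValidationError(f"eps_observed must be >= 0, got {eps_observed}")
    if pressure <= 0:
        raise ValidationError("pressure must be positive to estimate concentration")
    return eps_observed / (model.flow_per_pressure * pressure)


def adjust_pressure(
    current: float, eps_observed: float, model: InstrumentModel
) -> float:
    """One clamped multiplicative proportional control step toward the target rate.

    ``new = current * (eps_target / eps_observed) ** gain``; an observed rate
    of zero (sample line apparently empty) drives the pressure to maximum.
    """
    if not (np.isfinite(current) and np.isfinite(eps_observed)):
        raise ValidationError("pressure and event rate must be finite")
    if eps_observed == 0:
        logging.getLogger(__name__).warning(
            "observed event rate 0; driving pressure to maximum draw"
        )
        return model.pressure_max
    if eps_observed == model.eps_target:
        return current
    new = current * (model.eps_target / eps_observed) ** model.controller_gain
    return float(np.clip(new, model.pressure_min, model.pressure_max))


def _gate_membership(gate: GatePolygon, table: EventTable, axis: AxisMapping) -> np.ndarray:
    ix, iy = axis.indices(table)
    poly = shapely.Polygon(gate.vertices)
    shapely.prepare(poly)
    return shapely.intersects_xy(poly, table.values[:, ix], table.values[:, iy])


def run_session(
    table: EventTable,
    plan: SortPlan,
    model: InstrumentModel,
    seed: int,
    axis: AxisMapping | None = None,
    concentration: float = DEFAULT_CONCENTRATION,
    timing: SessionTiming = SessionTiming(),
) -> SortResult:
    """Simulate one sample's full session against a fitted gate.

    Profiles ``plan.n_profile`` events, then sorts until ``plan.n_sort``
    in-gate events are collected or the sample is exhausted (``completed``
    False with the shortfall recorded — never an exception). The pressure
    trace covers both streaming phases and stays within the instrument
    limits.
    """
    if plan.gate is None:
        raise ValidationError("plan.gate must be set (fit a gate on this sample first)")
    if axis is None:
        axis = plan.gate.axis
    in_gate = _gate_membership(plan.gate, table, axis)

    rng = np.random.default_rng(seed)
    dt = timing.control_dt
    pressure = 0.5 * (model.pressure_min + model.pressure_max)
    trace: list[tuple[float, float]] = []
    t = 0.0

    consumed = 0
    pressure_time_integral = 0.0
    profiled = 0

    def stream_until(stop_condition, cap: int) -> float:
        """Advance ticks until the condition on consumed events holds; returns elapsed."""
        nonlocal consumed, pressure, t, pressure_time_integral
        elapsed = 0.0
        while consumed < cap and not stop_condition():
            expected = concentration * model.flow_per_pressure * pressure * dt
            k = int(rng.poisson(expected))
            k = min(k, cap - consumed)
            consumed += k
            t += dt
            elapsed += dt
            pressure_time_integral += pressure * dt
            trace.append((t, pressure))
            pressure = adjust_pressure(pressure, k / dt, model)
        return elapsed

    # --- profiling phase ---
    profile_target = min(plan.n_profile, table.n_events)
    t_profile = stream_until(lambda: consumed >= profile_target, cap=profile_target)
    profiled = consumed
    if pressure_time_integral > 0:
        est_conc = profiled / (model.flow_per_pressure * pressure_time_integral)
    else:
        est_conc = 0.0

    # --- sorting phase ---
    sort_start = consumed
    sorted_count = 0

    def enough_sorted() -> bool:
        nonlocal sorted_count
        sorted_count = int(np.count_nonzero(in_gate[sort_start:consumed]))
        return sorted_count >= plan.n_sort

    t_sort = stream_until(enough_sorted, cap=table.n_events)
    # Trim overshoot within the final tick: stop at exactly n_sort collected.
    if sorted_count > plan.n_sort:
        hits = np.nonzero(in_gate[sort_start:consumed])[0]
        consumed = sort_start + int(hits[plan.n_sort - 1]) + 1
        sorted_count = plan.n_sort

    completed = sorted_count >= plan.n_sort
    phase_times = {
        "profiling": t_profile,
        "sorting": t_sort,
        "transport": timing.transport,
        "gating": timing.gating,
        "control": timing.control,
    }
    return SortResult(
        sample_id=table.sample_id,
        events_profiled=profiled,
        events_sorted=sorted_count,
        estimated_concentration=est_conc,
        pressure_trace=trace,
        phase_times=phase_times,
        completed=completed,
        shortfall=max(plan.n_sort - sorted_count, 0),
    )
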