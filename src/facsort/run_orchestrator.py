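"""Worklist-driven batch orchestration and end-of-run reporting.

A batch is described by a worklist: one row per sample giving its name, its
tube position in the 18-position housing and the destination well on the
96-well rescue plate. For each entry in order the orchestrator runs the
per-sample state machine (profile -> gate -> sort), routes warnings and
errors to a pluggable notification sink, and finally renders a summary
report (multi-page PDF with one gate-overlay panel per sample) next to a
machine-readable JSON summary.

Per-sample failures are isolated: a bad sample is marked failed with an
error notification naming the sample and phase, and the batch continues.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.backends.backend_pdf import PdfPages  # noqa: E402

from .density_contours import ContourPolygon, contour_at_mass, estimate_density, main_component
from .errors import (
    CapacityError,
    DuplicateEntryError,
    FacsortError,
    ValidationError,
    WellError,
    WorklistError,
)
from .event_io import AxisMapping, EventTable
from .gate_builder import GateConfig, GateFitResult, build_template_gate, fit_gate
from .notifications import LoggingSink, NotificationSink
from .sort_session import InstrumentModel, SessionTiming, SortPlan, SortResult, run_session
from .synthetic_cytometry import DEFAULT_AXIS

HOUSING_CAPACITY = 18
_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")

STATUSES = ("pending", "profiling", "gating", "sorting", "done", "failed", "skipped")
TERMINAL = ("done", "failed", "skipped")


def valid_wells() -> list[str]:
    """All 96 well labels of the rescue plate, row-major A1..H12."""
    return [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


@dataclass(frozen=True)
class WorklistEntry:
    sample_name: str
    tube_position: int
    destination_well: str

    def __post_init__(self) -> None:
        if not self.sample_name:
            raise WorklistError("sample name must be non-empty")
        if not 1 <= self.tube_position <= HOUSING_CAPACITY:
            raise CapacityError(
                f"tube position {self.tube_position} outside housing capacity "
                f"1..{HOUSING_CAPACITY}"
            )
        if not _WELL_RE.match(self.destination_well):
            raise WellError(
                f"invalid destination well {self.destination_well!r} (expected A1..H12)"
            )


def parse_worklist(path: str | Path) -> list[WorklistEntry]:
    """Read and validate a worklist CSV (columns: name, position, well)."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"name": str, "well": str})
    missing = {"name", "position", "well"} - set(frame.columns)
    if missing:
        raise WorklistError(f"{path}: missing column(s) {sorted(missing)}")
    entries = []
    for _, row in frame.iterrows():
        try:
            position = int(row["position"])
        except (TypeError, ValueError):
            raise WorklistError(f"{path}: non-integer position {row['position']!r}") from None
        entries.append(WorklistEntry(str(row["name"]), position, str(row["well"]).strip()))
    names = [e.sample_name for e in entries]
    positions = [e.tube_position for e in entries]
    for label, seq in (("sample name", names), ("tube position", positions)):
        dupes = {v for v in seq if seq.count(v) > 1}
        if dupes:
            raise DuplicateEntryError(f"{path}: duplicate {label}(s): {sorted(dupes)}")
    return entries


class RunState:
    """Per-sample status tracking with pause/resume/stop transitions.

    Exactly one sample is active at a time; terminal statuses (done, failed,
    skipped) are immutable.
    """

    def __init__(self, n_samples: int):
        self.statuses = ["pending"] * n_samples
        self.current: int | None = None
        self.paused = False
        self.stopped = False

    def set_status(self, index: int, status: str) -> None:
        if status not in STATUSES:
            raise ValidationError(f"unknown status {status!r}")
        if self.statuses[index] in TERMINAL:
            raise ValidationError(
                f"sample {index} already terminal ({self.statuses[index]}); cannot set {status}"
            )
        active = status not in TERMINAL and status != "pending"
        if active:
            if self.current is not None and self.current != index:
                raise ValidationError("another sample is already active")
            self.current = index
        elif self.current == index:
            self.current = None
        self.statuses[index] = status

    def pause(self) -> None:
        self.paused = True

    def resume(self) -> None:
        self.paused = False

    def stop(self) -> None:
        """Stop the run: every non-terminal sample is skipped."""
        self.stopped = True
        for i, s in enumerate(self.statuses):
            if s not in TERMINAL:
                self.statuses[i] = "skipped"
        self.current = None


@dataclass
class SampleOutcome:
    entry: WorklistEntry
    status: str
    fit: GateFitResult | None = None
    sort: SortResult | None = None
    contours: dict[float, ContourPolygon] = field(default_factory=dict)
    grid: Any = None
    profile: EventTable | None = None
    error: str | None = None


def run_batch(
    worklist: list[WorklistEntry],
    samples: dict[str, EventTable],
    *,
    axis: AxisMapping = DEFAULT_AXIS,
    gate_config: GateConfig = GateConfig(),
    instrument: InstrumentModel = InstrumentModel(),
    plan: SortPlan = SortPlan(),
    timing: SessionTiming = SessionTiming(),
    notifier: NotificationSink | None = None,
    seed: int = 0,
    control_sample: str | None = None,
    state: RunState | None = None,
) -> list[SampleOutcome]:
    """Process every worklist entry in order; failures never abort the batch.

    When ``control_sample`` names an entry, that sample is gated first and its
    height contour (back-scatter extent) seeds every other sample's template.
    """
    if not worklist:
        raise ValidationError("worklist is empty")
    notifier = notifier or LoggingSink()
    state = state or RunState(len(worklist))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(worklist)) % np.uint32(2**31)

    control_height: ContourPolygon | None = None
    if control_sample is not None:
        names = [e.sample_name for e in worklist]
        if control_sample not in names:
            raise ValidationError(f"control sample {control_sample!r} not in worklist")

    outcomes = [SampleOutcome(entry=e, status="pending") for e in worklist]
    order = list(range(len(worklist)))
    if control_sample is not None:
        i_ctrl = [e.sample_name for e in worklist].index(control_sample)
        order = [i_ctrl] + [i for i in order if i != i_ctrl]

    for i in order:
        entry = worklist[i]
        outcome = outcomes[i]
        if state.stopped or state.statuses[i] == "skipped":
            outcome.status = "skipped"
            continue
        name = entry.sample_name
        phase = "profiling"
        try:
            state.set_status(i, "profiling")
            table = samples.get(name)
            if table is None:
                raise ValidationError(f"no event data provided for sample {name!r}")
            profile = _profile_subsample(table, plan.n_profile, int(child_seeds[i]))
            grid = estimate_density(profile, axis)
            outcome.grid, outcome.profile = grid, profile

            phase = "gating"
            state.set_status(i, "gating")
            c_height = main_component(contour_at_mass(grid, gate_config.height_contour_mass))
            c_side = main_component(contour_at_mass(grid, gate_config.side_contour_mass))
            outcome.contours = {
                gate_config.height_contour_mass: c_height,
                gate_config.side_contour_mass: c_side,
            }
            if control_height is not None and name != control_sample:
                c_height = control_height
            template = build_template_gate(
                c_height,
                c_side,
                gate_config,
                axis=axis,
                transform_tags=dict(profile.transform_tags),
                sample_id=name,
            )
            fit = fit_gate(template, profile, axis, gate_config)
            outcome.fit = fit
            if name == control_sample:
                control_height = c_height
            if not fit.converged:
                notifier.warning(
                    f"gate did not converge (achieved {fit.achieved_fraction:.4f} "
                    f"vs target {gate_config.target_fraction:.4f})",
                    sample=name,
                    phase=phase,
                )

            phase = "sorting"
            state.set_status(i, "sorting")
            result = run_session(
                table,
                replace(plan, gate=fit.gate),
                instrument,
                seed=int(child_seeds[i]),
                axis=axis,
                timing=timing,
            )
            outcome.sort = result
            if not result.completed:
                notifier.warning(
                    f"sample exhausted {result.shortfall} events short of the sort count",
                    sample=name,
                    phase=phase,
                )
            state.set_status(i, "done")
            outcome.status = "done"
            notifier.info(
                f"done: sorted {result.events_sorted} events into "
                f"{entry.destination_well} (captured "
                f"{(fit.achieved_fraction if fit else 0) * 100:.2f}%)",
                sample=name,
                phase=phase,
            )
        except FacsortError as exc:
            state.set_status(i, "failed")
            outcome.status = "failed"
            outcome.error = str(exc)
            notifier.error(str(exc), sample=name, phase=phase)
    return outcomes


def _profile_subsample(table: EventTable, n_profile: int, seed: int) -> EventTable:
    if table.n_events <= n_profile:
        return table
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(table.n_events, size=n_profile, replace=False))
    return table.take(idx)


# ---------------------------------------------------------------------------
# Reporting


def summarize(outcomes: list[SampleOutcome]) -> dict[str, Any]:
    """Deterministic machine-readable batch summary."""
    records = []
    for o in outcomes:
        rec: dict[str, Any] = {
            "sample_name": o.entry.sample_name,
            "tube_position": o.entry.tube_position,
            "destination_well": o.entry.destination_well,
            "status": o.status,
            "error": o.error,
        }
        if o.fit is not None:
            rec["gate"] = {
                "achieved_fraction": o.fit.achieved_fraction,
                "converged": o.fit.converged,
                "translation": o.fit.translation,
                "rotation": o.fit.rotation,
                "n_vertices": o.fit.gate.n_vertices,
                "vertices": [[float(vx), float(vy)] for vx, vy in o.fit.gate.vertices],
            }
        if o.sort is not None:
            rec["sort"] = o.sort.to_dict()
        records.append(rec)
    return {"n_samples": len(outcomes), "samples": records}


def write_summary(outcomes: list[SampleOutcome], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(summarize(outcomes), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _header_table(ax, rows: list[list[str]]) -> None:
    ax.axis("off")
    table = ax.table(
        cellText=rows,
        colLabels=["Sample", "Pos", "Well", "Status", "Captured %", "Sorted"],
        loc="center",
        cellLoc="center",
    )
    table.auto_set_font_size(False)
    table.set_fontsize(8)
    ax.set_title("Batch summary", fontsize=12)


def _summary_rows(outcomes: list[SampleOutcome]) -> list[list[str]]:
    rows = []
    for o in outcomes:
        frac = f"{o.fit.achieved_fraction * 100:.2f}" if o.fit else "-"
        sorted_n = str(o.sort.events_sorted) if o.sort else "-"
        rows.append(
            [
                o.entry.sample_name,
                str(o.entry.tube_position),
                o.entry.destination_well,
                o.status,
                frac,
                sorted_n,
            ]
        )
    return rows


def render_report(
    outcomes: list[SampleOutcome],
    path: str | Path,
    include_timestamps: bool = False,
) -> Path:
    """Multi-page PDF: batch header table, then one panel per sample.

    Each sample panel overlays the fitted gate on the density and the height/
    side contours, annotated with the captured fraction and events sorted.
    With ``include_timestamps=False`` (the default) PDF creation dates are
    suppressed so identical inputs give byte-identical output.
    """
    if not outcomes:
        raise ValidationError("render_report needs at least one result")
    path = Path(path)
    metadata = {"Title": "facsort batch report"}
    if not include_timestamps:
        metadata["CreationDate"] = None  # type: ignore[assignment]
    with PdfPages(path, metadata=metadata) as pdf:
        fig, ax = plt.subplots(figsize=(8.5, 11))
        _header_table(ax, _summary_rows(outcomes))
        pdf.savefig(fig)
        plt.close(fig)
        for o in outcomes:
            fig, ax = plt.subplots(figsize=(8.5, 11))
            _render_sample_panel(ax, o)
            pdf.savefig(fig)
            plt.close(fig)
    summary_path = path.with_suffix(".json")
    write_summary(outcomes, summary_path)
    return path


def _render_sample_panel(ax, o: SampleOutcome) -> None:
    name = o.entry.sample_name
    if o.grid is not None:
        grid = o.grid
        ax.pcolormesh(
            grid.x_edges, grid.y_edges, grid.mass.T, cmap="Greys", rasterized=True
        )
    for level, contour in sorted(o.contours.items()):
        ring = np.vstack([contour.vertices, contour.vertices[:1]])
        ax.plot(ring[:, 0], ring[:, 1], lw=1.0, label=f"{level * 100:.0f}% contour")
    if o.fit is not None:
        ring = np.vstack([o.fit.gate.vertices, o.fit.gate.vertices[:1]])
        ax.plot(ring[:, 0], ring[:, 1], "r-", lw=1.5, label="gate")
    bits = [f"{name} ({o.status})"]
    if o.fit is not None:
        bits.append(f"captured {o.fit.achieved_fraction * 100:.2f}%")
    if o.sort is not None:
        bits.append(f"sorted {o.sort.events_sorted}")
    if o.error:
        bits.append(o.error)
    ax.set_title("; ".join(bits), fontsize=9)
    ax.set_xlabel("fluorescence (transformed)")
    ax.set_ylabel("back-scatter")
    if o.contours or o.fit is not None:
        ax.legend(loc="upper left", fontsize=7)


def render_from_summary(summary: dict[str, Any], path: str | Path) -> Path:
    """Re-render a report (gate outlines and stats only) from a JSON summary."""
    path = Path(path)
    with PdfPages(path, metadata={"CreationDate": None}) as pdf:  # type: ignore[dict-item]
        fig, ax = plt.subplots(figsize=(8.5, 11))
        rows = []
        for rec in summary["samples"]:
            gate = rec.get("gate")
            sort = rec.get("sort")
            rows.append(
                [
                    rec["sample_name"],
                    str(rec["tube_position"]),
                    rec["destination_well"],
                    rec["status"],
                    f"{gate['achieved_fraction'] * 100:.2f}" if gate else "-",
                    str(sort["events_sorted"]) if sort else "-",
                ]
            )
        _header_table(ax, rows)
        pdf.savefig(fig)
        plt.close(fig)
        for rec in summary["samples"]:
            gate = rec.get("gate")
            if not gate:
                continue
            fig, ax = plt.subplots(figsize=(8.5, 11))
            verts = np.array(gate["vertices"])
            ring = np.vstack([verts, verts[:1]])
            ax.plot(ring[:, 0], ring[:, 1], "r-", lw=1.5)
            ax.set_title(
                f"{rec['sample_name']}: captured {gate['achieved_fraction'] * 100:.2f}%",
                fontsize=9,
            )
            pdf.savefig(fig)
            plt.close(fig)
    return path
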