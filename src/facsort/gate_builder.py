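"""Sorting-gate construction and fitting.

The gate is a concave polygon (at most a fixed vertex budget, default 60) on
the (fluorescence, back-scatter) plane built from two density contours of the
profiled sample:

* the contour enclosing 80% of event mass sets the gate's *height* — the
  range of acceptable back-scatter;
* the contour enclosing 25% of event mass sets the *shape of the sides* —
  the gate's left boundary is that contour's high-fluorescence (rightmost)
  boundary arc, so the gate hugs the population's bright edge; the right
  boundary is the same curve shifted right by the 25%-contour's fluorescence
  span.

Where the 25% contour is shorter than the gate height, the side curves are
extended vertically at their endpoint fluorescence. The template is then
translated along the fluorescence axis — and, if needed, rotated about its
centroid — until it captures the user-defined top fraction of events
(default the brightest 1%). Fitting is fully deterministic.

Boundary events count as inside the gate: a consistent tie-break, since the
hardware's droplet-level decision at the exact boundary is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .density_contours import ContourPolygon
from .errors import (
    FormatError,
    GeometryError,
    InsufficientEventsError,
    TransformMismatchError,
    ValidationError,
)
from .event_io import AxisMapping, EventTable

MIN_FIT_EVENTS = 100


@dataclass(frozen=True)
class GateConfig:
    """Tunable parameters of gate construction and fitting.

    ``fraction_tolerance`` is absolute: 0.001 is ~50 events on a 50,000-event
    profile, finer than sampling noise at the default 1% target.
    """

    target_fraction: float = 0.01
    height_contour_mass: float = 0.80
    side_contour_mass: float = 0.25
    max_vertices: int = 60
    fraction_tolerance: float = 0.001
    max_rotation: float = 15.0  # degrees

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fraction < 1.0:
            raise ValidationError(f"target_fraction must be in (0,1), got {self.target_fraction}")
        for name in ("height_contour_mass", "side_contour_mass"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.max_vertices < 3:
            raise ValidationError(f"max_vertices must be >= 3, got {self.max_vertices}")
        if self.fraction_tolerance <= 0 or self.max_rotation < 0:
            raise ValidationError("fraction_tolerance must be > 0 and max_rotation >= 0")


@dataclass(frozen=True)
class GatePolygon:
    """Closed simple polygon in gating space, within the vertex budget.

    ``vertices`` is an open ring (the last vertex connects back to the first);
    ``transform_tags`` records the scale of each axis so the gate can refuse
    application to data in a different transform space.
    """

    vertices: np.ndarray
    axis: AxisMapping
    transform_tags: dict[str, str] = field(default_factory=dict)
    sample_id: str = ""

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=np.float64)
        object.__setattr__(self, "vertices", verts)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise ValidationError("gate needs an (n>=3, 2) vertex array")
        if not np.all(np.isfinite(verts)):
            raise ValidationError("gate vertices must be finite")
        ring = shapely.LinearRing(verts)
        if not ring.is_simple:
            raise GeometryError("gate ring is self-intersecting")
        if shapely.Polygon(verts).area <= 0:
            raise GeometryError("gate has zero area")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bsc_extent(self) -> tuple[float, float]:
        return float(self.vertices[:, 1].min()), float(self.vertices[:, 1].max())

    def transformed(self, dx: float = 0.0, rotation_deg: float = 0.0) -> "GatePolygon":
        """Copy rotated about the centroid then shifted along fluorescence."""
        verts = _place(self.vertices, self.centroid, dx, rotation_deg)
        return GatePolygon(verts, self.axis, dict(self.transform_tags), self.sample_id)


@dataclass(frozen=True)
class GateFitResult:
    gate: GatePolygon
    achieved_fraction: float
    translation: float
    rotation: float
    iterations: int
    converged: bool


def _place(verts: np.ndarray, pivot: np.ndarray, dx: float, rotation_deg: float) -> np.ndarray:
    out = verts - pivot
    if rotation_deg:
        t = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        out = out @ rot.T
    out = out + pivot
    out[:, 0] += dx
    return out


def rightmost_arc(ring: np.ndarray, y_values: np.ndarray) -> np.ndarray:
    """High-fluorescence boundary arc of a closed ring, sampled at given heights.

    For each height the arc point is the largest fluorescence at which a ring
    edge crosses that height; heights outside the ring's back-scatter range
    are clamped to the nearest extreme (vertical extension at constant
    fluorescence). Returns an (len(y_values), 2) polyline.
    """
    ring = np.asarray(ring, dtype=np.float64)
    closed = np.vstack([ring, ring[:1]])
    p, q = closed[:-1], closed[1:]
    y_lo, y_hi = float(ring[:, 1].min()), float(ring[:, 1].max())
    xs = np.empty(len(y_values))
    for k, y_raw in enumerate(np.asarray(y_values, dtype=np.float64)):
        y = min(max(y_raw, y_lo), y_hi)
        spans = (np.minimum(p[:, 1], q[:, 1]) <= y) & (y <= np.maximum(p[:, 1], q[:, 1]))
        sloped = spans & (p[:, 1] != q[:, 1])
        cand = p[sloped, 0] + (y - p[sloped, 1]) * (q[sloped, 0] - p[sloped, 0]) / (
            q[sloped, 1] - p[sloped, 1]
        )
        flat = spans & (p[:, 1] == q[:, 1])
        if flat.any():
            cand = np.concatenate([cand, p[flat, 0], q[flat, 0]])
        if cand.size == 0:  # degenerate ring slice; fall back to extreme vertex
            cand = ring[np.argmax(ring[:, 1] == y), :1]
        xs[k] = cand.max()
    return np.column_stack([xs, np.asarray(y_values, dtype=np.float64)])


def resample_ring(ring: np.ndarray, n: int) -> np.ndarray:
    """Arc-length resampling of a closed ring to exactly n vertices."""
    closed = np.vstack([ring, ring[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.column_stack(
        [np.interp(targets, s, closed[:, 0]), np.interp(targets, s, closed[:, 1])]
    )


def build_template_gate(
    contour80: ContourPolygon,
    contour25: ContourPolygon,
    config: GateConfig = GateConfig(),
    axis: AxisMapping | None = None,
    transform_tags: dict[str, str] | None = None,
    sample_id: str = "",
) -> GatePolygon:
    """Assemble the gate template from the height and side contours.

    Height = back-scatter extent of ``contour80``; left side = rightmost arc
    of ``contour25`` extended to that height; right side = left side shifted
    by the fluorescence span of ``contour25``; the ring stays within
    ``config.max_vertices`` (resampled by arc length if it would not).
    """
    y_lo, y_hi = contour80.bsc_extent()
    c25_lo, c25_hi = contour25.bsc_extent()
    if c25_hi < y_lo or c25_lo > y_hi:
        raise GeometryError(
            f"side-contour back-scatter range [{c25_lo:.3g}, {c25_hi:.3g}] does not "
            f"overlap height-contour range [{y_lo:.3g}, {y_hi:.3g}]"
        )
    x_min, x_max = contour25.fluo_extent()
    width = x_max - x_min
    if width <= 0:
        raise GeometryError("side contour has zero fluorescence span")

    n_side = max(config.max_vertices // 2, 2)
    ys = np.linspace(y_lo, y_hi, n_side)
    left = rightmost_arc(contour25.vertices, ys)
    right = left + np.array([width, 0.0])
    ring = np.vstack([left, right[::-1]])
    if len(ring) > config.max_vertices:
        ring = resample_ring(ring, config.max_vertices)
    return GatePolygon(
        ring,
        axis or AxisMapping("fluorescence", "backscatter"),
        dict(transform_tags or {}),
        sample_id,
    )


def _check_space(gate: GatePolygon, table: EventTable) -> None:
    for ch, tag in gate.transform_tags.items():
        have = table.transform_tags.get(ch)
        if have is not None and have != tag:
            raise TransformMismatchError(
                f"gate expects channel {ch!r} on {tag!r} scale but table carries {have!r}"
            )


def _fraction_inside(verts: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    poly = shapely.Polygon(verts)
    shapely.prepare(poly)
    return float(np.mean(shapely.intersects_xy(poly, x, y)))


def captured_fraction(gate: GatePolygon, table: EventTable, axis: AxisMapping) -> float:
    """Fraction of events inside or on the boundary of the gate."""
    if table.n_events == 0:
        raise ValidationError("captured_fraction undefined for an empty table")
    _check_space(gate, table)
    ix, iy = axis.indices(table)
    return _fraction_inside(gate.vertices, table.values[:, ix], table.values[:, iy])


_SCAN_POINTS = 65
_MAX_BISECT = 60
_GOLDEN_ITERS = 24
_INV_PHI = (np.sqrt(5.0) - 1.0) / 2.0


def fit_gate(
    template: GatePolygon,
    table: EventTable,
    axis: AxisMapping,
    config: GateConfig = GateConfig(),
) -> GateFitResult:
    """Translate (and if needed rotate) the template to capture the target fraction.

    Phase 1 brackets the target on the decreasing bright-side limb of the
    capture-vs-translation curve by a coarse scan, then bisects the
    translation. Phase 2, entered only if Phase 1 misses the tolerance,
    runs a golden-section search on rotation about the gate centroid within
    ±``max_rotation`` degrees, repeating Phase 1 at each candidate angle.
    An unreachable target yields the best gate flagged unconverged, never an
    exception.
    """
    if table.n_events < MIN_FIT_EVENTS:
        raise InsufficientEventsError(
            f"{table.sample_id!r}: {table.n_events} events < {MIN_FIT_EVENTS} required to fit"
        )
    _check_space(template, table)
    ix, iy = axis.indices(table)
    x, y = table.values[:, ix], table.values[:, iy]
    base, pivot = template.vertices, template.centroid
    target, tol = config.target_fraction, config.fraction_tolerance
    n_evals = 0

    def phase1(theta: float) -> tuple[float, float, int]:
        """Best (dx, achieved, iters) at fixed rotation."""
        nonlocal n_evals
        placed = _place(base, pivot, 0.0, theta)
        gx_lo, gx_hi = placed[:, 0].min(), placed[:, 0].max()
        dx_grid = np.linspace(x.min() - gx_hi, x.max() - gx_lo, _SCAN_POINTS)
        fracs = np.array(
            [_fraction_inside(_place(base, pivot, d, theta), x, y) for d in dx_grid]
        )
        n_evals += _SCAN_POINTS
        reachable = np.nonzero(fracs >= target)[0]
        if reachable.size == 0:  # target unreachable for this shape
            i_peak = int(np.argmax(fracs))
            return float(dx_grid[i_peak]), float(fracs[i_peak]), 0
        # Rightmost crossing: the capture curve may recross the target between
        # population modes; "top fraction" is the brightest-side crossing.
        i_last = int(reachable[-1])
        if i_last == _SCAN_POINTS - 1:
            return float(dx_grid[i_last]), float(fracs[i_last]), 0
        lo, hi = float(dx_grid[i_last]), float(dx_grid[i_last + 1])
        f_lo, f_hi = float(fracs[i_last]), float(fracs[i_last + 1])
        best_dx, best_f = (lo, f_lo) if abs(f_lo - target) <= abs(f_hi - target) else (hi, f_hi)
        span = x.max() - x.min()
        it = 0
        for it in range(1, _MAX_BISECT + 1):
            if abs(best_f - target) <= tol or hi - lo < 1e-12 * span:
                break
            mid = 0.5 * (lo + hi)
            f_mid = _fraction_inside(_place(base, pivot, mid, theta), x, y)
            n_evals += 1
            if abs(f_mid - target) < abs(best_f - target):
                best_dx, best_f = mid, f_mid
            if f_mid >= target:
                lo = mid
            else:
                hi = mid
        return best_dx, best_f, it

    dx0, f0, it0 = phase1(0.0)
    best = (0.0, dx0, f0, it0)
    if abs(f0 - target) > tol and config.max_rotation > 0:
        # Golden-section on |achieved - target| over rotation angle.
        a, b = -config.max_rotation, config.max_rotation
        cache: dict[float, tuple[float, float, int]] = {0.0: (dx0, f0, it0)}

        def err(theta: float) -> float:
            if theta not in cache:
                cache[theta] = phase1(theta)
            return abs(cache[theta][1] - target)

        c = b - _INV_PHI * (b - a)
        d = a + _INV_PHI * (b - a)
        for _ in range(_GOLDEN_ITERS):
            if err(c) < err(d):
                b, d = d, c
                c = b - _INV_PHI * (b - a)
            else:
                a, c = c, d
                d = a + _INV_PHI * (b - a)
            if abs(b - a) < 1e-3:
                break
        candidates = [(abs(res[1] - target), th, res) for th, res in cache.items()]
        _, theta_best, (dxb, fb, itb) = min(candidates, key=lambda t: (t[0], abs(t[1])))
        if abs(fb - target) < abs(best[2] - target):
            best = (theta_best, dxb, fb, itb)

    theta, dx, achieved, _ = best
    return GateFitResult(
        gate=template.transformed(dx=dx, rotation_deg=theta),
        achieved_fraction=achieved,
        translation=dx,
        rotation=theta,
        iterations=n_evals,
        converged=abs(achieved - target) <= tol,
    )


def export_gate(gate: GatePolygon, path: str | Path) -> None:
    """Write the gate as plain text: header lines, then one ``x,y`` per vertex.

    Float coordinates use 17 significant digits, so a read-back reproduces the
    gate bit for bit.
    """
    lines = [
        f"sample_id={gate.sample_id}",
        f"fluorescence_channel={gate.axis.fluorescence_channel}",
        f"backscatter_channel={gate.axis.backscatter_channel}",
    ]
    for ch in (gate.axis.fluorescence_channel, gate.axis.backscatter_channel):
        lines.append(f"transform[{ch}]={gate.transform_tags.get(ch, 'linear')}")
    lines += [f"{vx:.17g},{vy:.17g}" for vx, vy in gate.vertices]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gate(path: str | Path) -> GatePolygon:
    """Read a gate written by :func:`export_gate`."""
    path = Path(path)
    header: dict[str, str] = {}
    verts: list[tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if "=" in line and not verts:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'x,y', got {line!r}")
        try:
            verts.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric vertex {line!r}") from None
    for key in ("fluorescence_channel", "backscatter_channel"):
        if key not in header:
            raise FormatError(f"{path}: missing header line {key}=...")
    axis = AxisMapping(header["fluorescence_channel"], header["backscatter_channel"])
    tags = {
        ch: header.get(f"transform[{ch}]", "linear")
        for ch in (axis.fluorescence_channel, axis.backscatter_channel)
    }
    return GatePolygon(np.array(verts), axis, tags, header.get("sample_id", ""))
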